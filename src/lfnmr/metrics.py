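"""SNR definitions, cumulative-intensity metabolite bounds, LOD/LOQ logic.

Three signal-to-noise conventions are implemented:

* **integral** — signal and noise are the *mean absolute* intensities in
  their regions:

      SNR = ( sum_j |I(delta_j)| / n ) / ( sum_i |I(delta_i)| / m )

  This is the conservative convention used for all headline numbers;
  a broad signal window that includes baseline lowers it.

* **topspin_like** / **vnmrj_like** — signal is the *maximum absolute*
  intensity in the signal region, noise is the RMS of the mean-subtracted
  noise region; the topspin-like convention divides by twice that RMS,
  so vnmrj_like / topspin_like = 2 identically. These reconstruct the
  behaviour of the commercial ``sino`` / ``dsn`` routines, not their
  exact implementations.

Metabolite integration bounds are derived from a noiseless simulated
spectrum: the cumulative intensity, integrated from high to low ppm and
normalised to one, is cut at a quantile pair — [0.023, 0.977] brackets
~95.4% of the signal (the "2-sigma" region), [0.159, 0.841] ~68%. The
0.5 crossing defines the spectrum centre.

Conventional thresholds: limit of detection SNR = 3, limit of
quantification SNR = 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import NOISE_REGION, PpmInterval, Spectrum

__all__ = [
    "SnrResult",
    "BoundsSpec",
    "BoundsResult",
    "snr_integral",
    "snr_max_based",
    "compute_bounds",
    "threshold_crossings",
    "LOD_THRESHOLD",
    "LOQ_THRESHOLD",
]

LOD_THRESHOLD = 3.0
LOQ_THRESHOLD = 10.0


@dataclass(frozen=True)
class SnrResult:
    value: float
    method: str  # integral | topspin_like | vnmrj_like
    signal_region: PpmInterval
    noise_region: PpmInterval
    n_points_signal: int
    n_points_noise: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("SNR must be >= 0")


@dataclass(frozen=True)
class BoundsSpec:
    """Cumulative-quantile pair defining an integration region."""

    quantile_pair: tuple[float, float] = (0.023, 0.977)

    def __post_init__(self) -> None:
        lo, hi = self.quantile_pair
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"quantiles must satisfy 0 < lo < hi < 1, got {lo}, {hi}")

    @property
    def coverage(self) -> float:
        lo, hi = self.quantile_pair
        return hi - lo


TWO_SIGMA = BoundsSpec((0.023, 0.977))
ONE_SIGMA = BoundsSpec((0.159, 0.841))


@dataclass(frozen=True)
class BoundsResult:
    interval: PpmInterval
    centre: float  # ppm at which the cumulative sum crosses 0.5
    coverage: float  # fraction of total intensity inside the interval


def _regions_checked(spec: Spectrum, signal_region: PpmInterval,
                     noise_region: PpmInterval) -> tuple[np.ndarray, np.ndarray]:
    if signal_region.low < noise_region.high and noise_region.low < signal_region.high:
        raise ValueError("signal and noise regions must not overlap")
    sm = signal_region.mask(spec.axis)
    nm = noise_region.mask(spec.axis)
    if not sm.any():
        raise ValueError(f"signal region {signal_region} is empty on this axis")
    if not nm.any():
        raise ValueError(f"noise region {noise_region} is empty on this axis")
    return sm, nm


def snr_integral(spec: Spectrum, signal_region: PpmInterval,
                 noise_region: PpmInterval = NOISE_REGION) -> SnrResult:
    """Mean-absolute-intensity SNR (the conservative integral convention)."""
    sm, nm = _regions_checked(spec, signal_region, noise_region)
    signal = float(np.abs(spec.intensities[sm]).mean())
    noise = float(np.abs(spec.intensities[nm]).mean())
    if noise == 0.0:
        raise ZeroDivisionError(
            "noise region has zero mean absolute intensity; the integral SNR "
            "denominator is degenerate")
    return SnrResult(value=signal / noise, method="integral",
                     signal_region=signal_region, noise_region=noise_region,
                     n_points_signal=int(sm.sum()), n_points_noise=int(nm.sum()))


def snr_max_based(spec: Spectrum, signal_region: PpmInterval,
                  noise_region: PpmInterval = NOISE_REGION,
                  convention: str = "topspin_like") -> SnrResult:
    """Max-signal SNR in the topspin-like or vnmrj-like convention.

    signal = max |I| over the signal region; noise = RMS of the
    mean-subtracted noise region. The vnmrj-like value is signal/noise,
    the topspin-like value signal/(2 x noise), so their ratio is exactly 2.
    """
    if convention not in ("topspin_like", "vnmrj_like"):
        raise ValueError(f"unknown convention {convention!r}")
    sm, nm = _regions_checked(spec, signal_region, noise_region)
    signal = float(np.abs(spec.intensities[sm]).max())
    noise_pts = spec.intensities[nm]
    noise = float(np.sqrt(np.mean((noise_pts - noise_pts.mean()) ** 2)))
    if noise == 0.0:
        raise ZeroDivisionError(
            "noise region has zero RMS; the max-based SNR denominator is "
            "degenerate")
    value = signal / noise
    if convention == "topspin_like":
        value /= 2.0
    return SnrResult(value=value, method=convention,
                     signal_region=signal_region, noise_region=noise_region,
                     n_points_signal=int(sm.sum()), n_points_noise=int(nm.sum()))


def _crossing(cum: np.ndarray, axis: np.ndarray, q: float) -> float:
    """ppm at which the cumulative fraction first crosses q.

    The cumulative sum runs in integration direction (high -> low ppm);
    the first index where it reaches q is used and the crossing is
    linearly interpolated between the bracketing grid points.
    """
    idx = int(np.searchsorted(cum, q))
    if idx == 0:
        return float(axis[0])
    if idx >= cum.size:
        return float(axis[-1])
    c0, c1 = cum[idx - 1], cum[idx]
    if c1 == c0:
        return float(axis[idx])
    frac = (q - c0) / (c1 - c0)
    return float(axis[idx - 1] + frac * (axis[idx] - axis[idx - 1]))


def compute_bounds(sim: Spectrum, spec: BoundsSpec = TWO_SIGMA,
                   window: PpmInterval | None = None) -> BoundsResult:
    """Quantile bounds of a (noiseless) simulated spectrum.

    The intensity is cumulated from high to low ppm and normalised to
    one; the returned interval spans the quantile pair and ``centre``
    is the 0.5 crossing. ``window`` optionally restricts the analysis
    (e.g. to exclude anomeric glucose signal overlapping the water
    region) before the cumulative sum is formed.
    """
    axis = sim.axis
    y = sim.intensities
    if window is not None:
        m = window.mask(axis)
        axis, y = axis[m], y[m]
    total = y.sum()
    if total <= 0:
        raise ValueError("cannot compute bounds on non-positive total intensity")
    cum = np.cumsum(y) / total

    q_lo, q_hi = spec.quantile_pair
    high_edge = _crossing(cum, axis, q_lo)  # early in integration = high ppm
    centre = _crossing(cum, axis, 0.5)
    low_edge = _crossing(cum, axis, q_hi)
    interval = PpmInterval(min(low_edge, high_edge), max(low_edge, high_edge))
    inside = interval.mask(axis)
    coverage = float(y[inside].sum() / total)
    return BoundsResult(interval=interval, centre=centre, coverage=coverage)


def threshold_crossings(series: Sequence[tuple[int, SnrResult | float]],
                        thresholds: Mapping[str, float] | Iterable[float] = None,
                        ) -> dict:
    """Smallest scan count at which each SNR threshold is reached.

    ``series`` is a list of (n_scans, SNR) sorted by n_scans; SNR may be
    a bare float or an SnrResult. Returns {label: n_scans or None}; None
    flags a threshold never reached within the series.
    """
    if len(series) == 0:
        raise ValueError("empty SNR series")
    if thresholds is None:
        thresholds = {"LOD": LOD_THRESHOLD, "LOQ": LOQ_THRESHOLD}
    if not isinstance(thresholds, Mapping):
        thresholds = {f"SNR>={t:g}": float(t) for t in thresholds}
    scans = [int(n) for n, _ in series]
    if scans != sorted(scans):
        raise ValueError("series must be sorted by n_scans")
    values = [s.value if isinstance(s, SnrResult) else float(s)
              for _, s in series]
    out: dict[str, int | None] = {}
    for label, thr in thresholds.items():
        out[label] = next((n for n, v in zip(scans, values) if v >= thr), None)
    return out
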