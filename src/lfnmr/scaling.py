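"""Signal ratios, scan-series stability and power-law SNR scaling.

Relative metabolite quantification uses the ratio of summed intensities

    R_XY = S_X / S_Y = sum_j I_X(delta_j) / sum_i I_Y(delta_i)

over each metabolite's chemical-shift bounds. Signed (not absolute)
intensities are summed, so a noise-dominated experimental region can
legitimately come out near zero or negative — exactly the instability
template fitting is meant to remove. In "experimental" mode the sums run
over the measured spectrum; in "simulation" mode over fitted template
components, whose amplitudes are pinned to known multiplet shapes.

Scan-averaging theory predicts SNR growing as sqrt(n_scans); the
power-law fit SNR = A * n_scans^B (ordinary least squares in log-log
space) quantifies how closely a series follows that, and rescaling the
fitted amplitude A by a concentration factor predicts the series of a
proportionally diluted sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import SnrResult
from .template_fit import TemplateFitResult
from .types import PpmInterval, Spectrum

__all__ = [
    "RatioResult",
    "PowerLawFit",
    "RescalePrediction",
    "signal_ratio",
    "signal_ratio_from_fits",
    "ratio_series",
    "ratio_stability",
    "fit_power_law",
    "rescale_prediction",
]


@dataclass(frozen=True)
class RatioResult:
    numerator: str
    denominator: str
    value: float
    uncertainty: float  # one sigma
    source: str  # experimental-integration | simulation-fit
    n_scans: int | None = None

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def _region_sum(axis: np.ndarray, y: np.ndarray, bounds: PpmInterval
                ) -> tuple[float, int]:
    m = bounds.mask(axis)
    if not m.any():
        raise ValueError(f"no axis points inside {bounds}")
    return float(y[m].sum()), int(m.sum())


def signal_ratio(spec: Spectrum, bounds_x: PpmInterval, bounds_y: PpmInterval,
                 noise_region: PpmInterval | None = None,
                 labels: tuple[str, str] = ("X", "Y")) -> RatioResult:
    """Experimental-integration signal ratio with noise-propagated uncertainty.

    The one-sigma uncertainty of a summed region is (noise RMS) x
    sqrt(number of points in the region) — independent noise per point —
    propagated to the ratio to first order. Without a noise region the
    uncertainty is reported as zero (noiseless input).
    """
    sx, n_x = _region_sum(spec.axis, spec.intensities, bounds_x)
    sy, n_y = _region_sum(spec.axis, spec.intensities, bounds_y)
    if sy == 0.0:
        raise ZeroDivisionError(f"denominator sum over {bounds_y} is zero")
    value = sx / sy
    sigma = 0.0
    if noise_region is not None:
        pts = spec.intensities[noise_region.mask(spec.axis)]
        rms = float(np.sqrt(np.mean((pts - pts.mean()) ** 2)))
        sig_x = rms * np.sqrt(n_x)
        sig_y = rms * np.sqrt(n_y)
        sigma = abs(value) * np.hypot(sig_x / sx if sx != 0 else 0.0,
                                      sig_y / sy)
    return RatioResult(numerator=labels[0], denominator=labels[1], value=value,
                       uncertainty=float(sigma), source="experimental-integration",
                       n_scans=spec.meta.get("n_scans"))


def signal_ratio_from_fits(axis: np.ndarray, fit_x: TemplateFitResult,
                           fit_y: TemplateFitResult, bounds_x: PpmInterval,
                           bounds_y: PpmInterval,
                           n_scans: int | None = None) -> RatioResult:
    """Simulation-fit signal ratio from fitted template components.

    Each summed signal is proportional to the fitted amplitude, so its
    relative uncertainty equals sd(A_rel)/A_rel from the fit covariance;
    an A_rel of zero (baseline fit) contributes sd(A_rel) x (component
    sum at unit amplitude) absolutely.
    """
    sx, n_x = _region_sum(axis, fit_x.component, bounds_x)
    sy, n_y = _region_sum(axis, fit_y.component, bounds_y)
    if sy == 0.0:
        raise ZeroDivisionError(
            f"denominator fit ({fit_y.species}) sums to zero over {bounds_y}")
    value = sx / sy

    # each sum is proportional to its fitted amplitude, so relative
    # uncertainties transfer directly; a baseline fit (A_rel = 0) sums to
    # zero and contributes zero numerator with sd(A_rel)-limited resolution
    rel_x = fit_x.a_rel_sd / fit_x.a_rel if fit_x.a_rel > 0 else 0.0
    rel_y = fit_y.a_rel_sd / fit_y.a_rel if fit_y.a_rel > 0 else 0.0
    sigma = abs(value) * np.hypot(rel_x, rel_y)
    return RatioResult(numerator=fit_x.species, denominator=fit_y.species,
                       value=value, uncertainty=float(abs(sigma)),
                       source="simulation-fit", n_scans=n_scans)


def ratio_series(spectra: Sequence[Spectrum], template_x, template_y,
                 bounds_x: PpmInterval, bounds_y: PpmInterval,
                 noise_region: PpmInterval | None = None
                 ) -> list[RatioResult]:
    """Both ratio estimators across a scan series, sorted by scan count.

    The experimental-integration ratio is computed per spectrum directly.
    For the simulation-fit ratio the nonlinear lineshape parameters
    (width, shift) are estimated once on the highest-scan-count spectrum
    and held fixed for linear amplitude-only fits on every member — the
    free shape parameters would otherwise add variance at low SNR that
    the template constraint exists to remove.
    """
    from .template_fit import fit_amplitude, fit_template

    if not spectra:
        raise ValueError("need a non-empty spectrum series")
    ordered = sorted(spectra, key=lambda s: s.meta.get("n_scans") or 0)
    best = ordered[-1]
    shape_x = fit_template(best, template_x, bounds_x)
    shape_y = fit_template(best, template_y, bounds_y)
    results: list[RatioResult] = []
    for spec in ordered:
        n = spec.meta.get("n_scans")
        results.append(signal_ratio(spec, bounds_x, bounds_y,
                                    noise_region=noise_region,
                                    labels=(template_x.species,
                                            template_y.species)))
        fx = fit_amplitude(spec, template_x, bounds_x,
                           shape_x.width_hz, shape_x.shift_ppm)
        fy = fit_amplitude(spec, template_y, bounds_y,
                           shape_y.width_hz, shape_y.shift_ppm)
        results.append(signal_ratio_from_fits(spec.axis, fx, fy,
                                              bounds_x, bounds_y, n_scans=n))
    return results


@dataclass(frozen=True)
class StabilitySummary:
    source: str
    std: float  # standard deviation of the ratio across scan counts
    reference_value: float  # ratio at the highest scan count
    fidelity_floor: int | None  # smallest n with all n' >= n within tolerance
    tolerance: float


def ratio_stability(series: Sequence[RatioResult],
                    tolerance: float = 0.2) -> dict[str, StabilitySummary]:
    """Per-source spread of a ratio series across scan counts.

    Taking the highest-scan-count ratio of each source as its ground
    truth, the fidelity floor is the smallest scan count from which the
    ratio stays within ``tolerance`` (relative) of that reference all
    the way up the series.
    """
    if len(series) < 3:
        raise ValueError("need ratios at >= 3 scan counts")
    by_source: dict[str, list[RatioResult]] = {}
    for r in series:
        if r.n_scans is None:
            raise ValueError("every RatioResult needs n_scans for a stability "
                             "analysis")
        by_source.setdefault(r.source, []).append(r)
    out: dict[str, StabilitySummary] = {}
    for source, rs in by_source.items():
        rs = sorted(rs, key=lambda r: r.n_scans)
        values = np.array([r.value for r in rs])
        ref = values[-1]
        within = np.abs(values - ref) <= tolerance * abs(ref)
        floor = None
        for i in range(len(rs)):
            if within[i:].all():
                floor = rs[i].n_scans
                break
        out[source] = StabilitySummary(source=source, std=float(values.std()),
                                       reference_value=float(ref),
                                       fidelity_floor=floor,
                                       tolerance=tolerance)
    return out


@dataclass(frozen=True)
class PowerLawFit:
    """SNR = A * n_scans^B fitted by OLS in log-log space."""

    amplitude: float  # A: SNR at one scan
    exponent: float  # B
    r_squared: float
    scan_counts: tuple[int, ...]  # points actually used
    snr_floor: float | None = None

    def predict(self, n_scans) -> np.ndarray:
        return self.amplitude * np.asarray(n_scans, dtype=float) ** self.exponent


def fit_power_law(series: Sequence[tuple[int, SnrResult | float]],
                  snr_floor: float | None = None) -> PowerLawFit:
    """Fit log(SNR) = log(A) + B log(n_scans) by unweighted least squares.

    Points at or below ``snr_floor`` (when given) are excluded — the
    standard remedy when a noise-dominated low-scan tail flattens the
    apparent exponent.
    """
    scans = np.array([int(n) for n, _ in series], dtype=float)
    snr = np.array([s.value if isinstance(s, SnrResult) else float(s)
                    for _, s in series])
    if np.any(snr <= 0):
        raise ValueError("all SNR values must be > 0 for a log-log fit")
    keep = np.ones_like(snr, dtype=bool)
    if snr_floor is not None:
        keep = snr > snr_floor
    if keep.sum() < 2:
        raise ValueError(
            f"need >= 2 points above the SNR floor, have {int(keep.sum())}")
    lx, ly = np.log(scans[keep]), np.log(snr[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = intercept + slope * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(amplitude=float(np.exp(intercept)), exponent=float(slope),
                       r_squared=r2,
                       scan_counts=tuple(int(n) for n in scans[keep]),
                       snr_floor=snr_floor)


@dataclass(frozen=True)
class RescalePrediction:
    factor: float
    scan_counts: tuple[int, ...]
    predicted: tuple[float, ...]
    r_squared: float | None  # vs observed, in log-log space; None if unobserved
    max_relative_deviation: float | None


def rescale_prediction(fit: PowerLawFit, factor: float,
                       observed: Sequence[tuple[int, SnrResult | float]] | None = None
                       ) -> RescalePrediction:
    """Predict a diluted sample's SNR series as factor * A * n^B.

    Signal is linear in concentration, so halving the concentration
    should halve the power-law amplitude while leaving the exponent at
    ~1/2. When an observed series is supplied, agreement is summarised
    by the log-log R^2 and the maximum relative deviation.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if observed is not None:
        scans = tuple(int(n) for n, _ in observed)
        obs = np.array([s.value if isinstance(s, SnrResult) else float(s)
                        for _, s in observed])
    else:
        scans = fit.scan_counts
        obs = None
    pred = factor * fit.predict(scans)
    r2 = None
    maxdev = None
    if obs is not None:
        if np.any(obs <= 0):
            raise ValueError("observed SNR values must be > 0")
        ly, lp = np.log(obs), np.log(pred)
        ss_res = float(np.sum((ly - lp) ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        maxdev = float(np.max(np.abs(pred - obs) / obs))
    return RescalePrediction(factor=factor, scan_counts=scans,
                             predicted=tuple(float(p) for p in pred),
                             r_squared=r2, max_relative_deviation=maxdev)
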