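"""Shared containers for spectra, intervals and mixtures.

Conventions used throughout the package:

* chemical shift axes are in ppm, stored **high-to-low** (NMR display
  order, and the direction in which cumulative bounds are integrated);
* scalar couplings and linewidths are in Hz;
* concentrations are in mmol/L;
* intensities are in arbitrary units in which one proton at 1 mmol/L
  contributes unit integrated area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PpmInterval",
    "Spectrum",
    "SimulatedSpectrum",
    "MixtureSpec",
    "make_axis",
]

#: default point spacing of the synthetic acquisitions, in ppm
DEFAULT_PPM_STEP = 6.1487e-4


def make_axis(high: float = 10.0, low: float = -2.5,
              step: float = DEFAULT_PPM_STEP) -> np.ndarray:
    """Build a canonical high-to-low ppm grid with constant spacing."""
    if high <= low:
        raise ValueError(f"axis requires high > low, got [{low}, {high}]")
    n = int(np.floor((high - low) / step)) + 1
    return high - step * np.arange(n)


@dataclass(frozen=True)
class PpmInterval:
    """A closed chemical-shift interval [low, high] in ppm."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"PpmInterval requires low < high, got [{self.low}, {self.high}]")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def centre(self) -> float:
        return 0.5 * (self.low + self.high)

    def mask(self, axis: np.ndarray) -> np.ndarray:
        """Boolean mask of axis points inside the closed interval."""
        return (axis >= self.low) & (axis <= self.high)

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


def _validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be a 1-D array with at least 2 points")
    d = np.diff(axis)
    if not (np.all(d < 0) or np.all(d > 0)):
        raise ValueError("axis must be strictly monotone")
    return axis


@dataclass
class Spectrum:
    """A 1-D spectrum: ppm axis plus intensities and acquisition metadata.

    ``meta`` carries free-form acquisition state; well-known keys are
    ``n_scans``, ``profile``, ``spectrometer_freq_mhz``, ``scaling``
    ("unscaled" | "scaled"), ``aligned`` (bool) and ``duration_s``.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.axis.shape:
            raise ValueError("axis and intensities must have the same length")

    def copy(self, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.axis.copy(), self.intensities.copy(), meta)

    def slice(self, interval: PpmInterval) -> tuple[np.ndarray, np.ndarray]:
        """Return (axis, intensities) restricted to a closed ppm interval."""
        m = interval.mask(self.axis)
        if not m.any():
            raise ValueError(f"no axis points inside {interval}")
        return self.axis[m], self.intensities[m]


@dataclass
class SimulatedSpectrum(Spectrum):
    """A noiseless simulated spectrum with per-species components.

    Invariant: the pointwise sum of the component vectors equals the
    total intensities (to numerical precision).
    """

    components: Mapping[str, np.ndarray] = field(default_factory=dict)

    def component_spectrum(self, name: str) -> Spectrum:
        return Spectrum(self.axis.copy(), np.asarray(self.components[name]),
                        dict(self.meta))


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of a synthetic sample.

    ``species`` lists (name, concentration mmol/L) pairs; the chemical
    shift reference (TSP) is carried separately because every sample
    contains it at a fixed concentration. Residual water is described
    phenomenologically by its position and its amplitude relative to
    the tallest metabolite peak.
    """

    species: tuple[tuple[str, float], ...]
    reference_concentration: float = 0.1  # TSP, mmol/L
    water_ppm: float = 4.8
    water_scale: float = 200.0  # water peak height / tallest metabolite peak

    def __post_init__(self) -> None:
        for name, conc in self.species:
            if conc < 0:
                raise ValueError(f"negative concentration for {name}: {conc}")
        if self.reference_concentration < 0:
            raise ValueError("reference_concentration must be >= 0")


#: the mixed reference sample analysed throughout: glucose 10, lactate 2,
#: citrate 0.2 mmol/L with 0.1 mmol/L TSP and residual water ~200x the
#: tallest metabolite peak.
MIXED_SAMPLE = MixtureSpec(
    species=(("glucose", 10.0), ("lactate", 2.0), ("citrate", 0.2)),
)

#: standard metabolite integration windows (ppm) used for SNR and ratios
METABOLITE_BOUNDS = {
    "glucose": PpmInterval(3.19, 3.98),
    "lactate": PpmInterval(1.17, 1.50),
    "citrate": PpmInterval(2.37, 2.82),
}

#: standard noise window for SNR computation
NOISE_REGION = PpmInterval(-2.0, -1.0)
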