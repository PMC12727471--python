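"""Quantum-mechanical simulation of liquid-state 1H spin systems.

A metabolite is described by a :class:`SpinSystem` — isotropic chemical
shifts (ppm) and a symmetric scalar-coupling matrix (Hz). The spectrum
is computed from the full spin-1/2 Hamiltonian

    H / h = sum_i  nu_i I_z,i  +  sum_{i<j} J_ij (I_i . I_j),

with nu_i = delta_i x f_spec (Hz at the stated spectrometer frequency).
Diagonalising H and evaluating the total lowering operator between
eigenstates yields a list of (frequency, intensity) transitions. This
treatment is exact and therefore captures the strong-coupling (second
order) distortions that dominate multiplet shapes at low field, where
shift separations in Hz become comparable to the couplings.

Transitions are rendered as Lorentzian lines whose integrated area is
proportional to transition intensity times concentration, so that the
total area of a species equals (number of protons) x (mmol/L) in the
package's intensity units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import MixtureSpec, PpmInterval, SimulatedSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SpinSystem",
    "TransitionList",
    "compute_transitions",
    "render_spectrum",
    "simulate_mixture",
    "lorentzian",
    "MAX_SPINS",
    "MAX_COUPLED_SPINS",
]

#: hard cap on the number of spins in one system
MAX_SPINS = 16
#: hard cap on the size of one *coupled* cluster (Hilbert space 2^10)
MAX_COUPLED_SPINS = 10
#: transitions carrying less than this fraction of the total intensity
#: are dropped (numerical hygiene; configurable per call)
DEFAULT_INTENSITY_FLOOR = 1e-8

# single spin-1/2 operators (hbar = 1 units; eigenvalues of Iz are +-1/2)
_IX = np.array([[0.0, 0.5], [0.5, 0.0]])
_IY = np.array([[0.0, -0.5j], [0.5j, 0.0]])
_IZ = np.array([[0.5, 0.0], [0.0, -0.5]])
_IMINUS = np.array([[0.0, 0.0], [1.0, 0.0]])
_ID = np.eye(2)


@dataclass(frozen=True)
class SpinSystem:
    """One molecular species: shifts, couplings and a molar population.

    ``population`` is the relative molar fraction used when a named
    metabolite is a mixture of forms (e.g. the 36:64 alpha:beta
    equilibrium of D-glucose anomers).
    """

    name: str
    shifts: tuple[float, ...]
    couplings: tuple[tuple[float, ...], ...]
    population: float = 1.0
    equivalence_groups: tuple[tuple[int, ...], ...] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.shifts)
        if n < 1:
            raise ValueError(f"{self.name}: spin system needs at least one spin")
        if n > MAX_SPINS:
            raise ValueError(
                f"{self.name}: {n} spins exceeds the supported maximum of "
                f"{MAX_SPINS} spins per system")
        J = np.asarray(self.couplings, dtype=float)
        if J.shape != (n, n):
            raise ValueError(
                f"{self.name}: coupling matrix must be {n}x{n}, got {J.shape}")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError(f"{self.name}: coupling matrix must be symmetric")
        if not np.allclose(np.diag(J), 0.0):
            raise ValueError(f"{self.name}: coupling matrix diagonal must be zero")
        if self.population < 0:
            raise ValueError(f"{self.name}: population must be >= 0")

    @property
    def n_spins(self) -> int:
        return len(self.shifts)

    @property
    def coupling_matrix(self) -> np.ndarray:
        return np.asarray(self.couplings, dtype=float)

    @classmethod
    def from_arrays(cls, name: str, shifts: Sequence[float],
                    couplings: np.ndarray, population: float = 1.0,
                    source_id: str = "") -> "SpinSystem":
        J = np.asarray(couplings, dtype=float)
        return cls(name=name, shifts=tuple(float(s) for s in shifts),
                   couplings=tuple(tuple(float(x) for x in row) for row in J),
                   population=population, source_id=source_id)


@dataclass(frozen=True)
class TransitionList:
    """Single-quantum transitions of one spin system.

    Frequencies are in Hz relative to the 0-ppm reference at the stated
    spectrometer frequency; intensities are dimensionless and sum to the
    number of observable protons.
    """

    frequencies_hz: np.ndarray
    intensities: np.ndarray
    n_spins: int
    spectrometer_freq_mhz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies_hz",
                           np.asarray(self.frequencies_hz, dtype=float))
        object.__setattr__(self, "intensities",
                           np.asarray(self.intensities, dtype=float))
        if np.any(self.intensities < 0):
            raise ValueError("transition intensities must be >= 0")

    @property
    def positions_ppm(self) -> np.ndarray:
        return self.frequencies_hz / self.spectrometer_freq_mhz

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    def __len__(self) -> int:
        return self.frequencies_hz.size


def _kron_chain(ops: Iterable[np.ndarray]) -> np.ndarray:
    return reduce(np.kron, ops)


def _single_spin_op(op: np.ndarray, index: int, n: int) -> np.ndarray:
    return _kron_chain([_ID] * index + [op] + [_ID] * (n - index - 1))


def _coupled_clusters(J: np.ndarray) -> list[list[int]]:
    """Connected components of the coupling graph (union-find)."""
    n = J.shape[0]
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if J[i, j] != 0.0:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def _cluster_transitions(shifts_hz: np.ndarray, J: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exact transitions of one coupled cluster by dense diagonalisation."""
    n = shifts_hz.size
    if n == 1:
        # Zeeman-only: a single line of unit intensity
        return np.array([shifts_hz[0]]), np.array([1.0])

    dim = 2 ** n
    H = np.zeros((dim, dim))
    ix = [_single_spin_op(_IX, i, n) for i in range(n)]
    iy = [_single_spin_op(_IY, i, n) for i in range(n)]
    iz = [_single_spin_op(_IZ, i, n) for i in range(n)]
    for i in range(n):
        H += shifts_hz[i] * iz[i]
    for i in range(n):
        for j in range(i + 1, n):
            if J[i, j] != 0.0:
                term = (ix[i] @ ix[j]).real + (iy[i] @ iy[j]).real + iz[i] @ iz[j]
                H += J[i, j] * term

    energies, vecs = np.linalg.eigh(H)
    i_minus = sum(_single_spin_op(_IMINUS, i, n) for i in range(n))
    # matrix elements of the total lowering operator between eigenstates;
    # only pairs differing by one magnetic quantum number are non-zero
    elems = vecs.T @ i_minus @ vecs
    weights = elems ** 2 / 2 ** (n - 1)
    f_idx, i_idx = np.nonzero(weights > 0.0)
    freqs = energies[i_idx] - energies[f_idx]
    return freqs, weights[f_idx, i_idx]


def _merge_degenerate(freqs: np.ndarray, intens: np.ndarray,
                      tol_hz: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(freqs)
    f, w = freqs[order], intens[order]
    out_f: list[float] = []
    out_w: list[float] = []
    for fi, wi in zip(f, w):
        if out_f and fi - out_f[-1] < tol_hz:
            # weighted-mean position keeps line centroids exact
            tot = out_w[-1] + wi
            out_f[-1] = (out_f[-1] * out_w[-1] + fi * wi) / tot
            out_w[-1] = tot
        else:
            out_f.append(float(fi))
            out_w.append(float(wi))
    return np.array(out_f), np.array(out_w)


def compute_transitions(system: SpinSystem, spectrometer_freq: float,
                        intensity_floor: float = DEFAULT_INTENSITY_FLOOR
                        ) -> TransitionList:
    """Exact single-quantum transitions of ``system`` at ``spectrometer_freq`` MHz.

    The coupling graph is split into independent coupled clusters; each
    cluster's Hamiltonian is diagonalised exactly, so strong-coupling
    intensity redistribution ("roofing") is fully represented. Transitions
    below ``intensity_floor`` x (total intensity) are pruned.
    """
    if spectrometer_freq <= 0:
        raise ValueError("spectrometer_freq must be > 0 (MHz)")
    J = system.coupling_matrix
    shifts_hz = np.asarray(system.shifts) * spectrometer_freq

    all_f: list[np.ndarray] = []
    all_w: list[np.ndarray] = []
    for cluster in _coupled_clusters(J):
        if len(cluster) > MAX_COUPLED_SPINS:
            raise ValueError(
                f"{system.name}: coupled cluster of {len(cluster)} spins exceeds "
                f"the supported maximum of {MAX_COUPLED_SPINS} mutually coupled "
                f"spins (Hilbert space 2^{MAX_COUPLED_SPINS})")
        idx = np.array(cluster)
        f, w = _cluster_transitions(shifts_hz[idx], J[np.ix_(idx, idx)])
        all_f.append(f)
        all_w.append(w)

    freqs = np.concatenate(all_f)
    intens = np.concatenate(all_w)
    freqs, intens = _merge_degenerate(freqs, intens)
    total = intens.sum()
    keep = intens >= intensity_floor * total
    return TransitionList(frequencies_hz=freqs[keep], intensities=intens[keep],
                          n_spins=system.n_spins,
                          spectrometer_freq_mhz=spectrometer_freq)


def lorentzian(x: np.ndarray, centre: float, fwhm: float,
               area: float = 1.0) -> np.ndarray:
    """Lorentzian line with unit-area normalisation: peak height 2a/(pi w)."""
    return (2.0 * area / (np.pi * fwhm)) / (1.0 + (2.0 * (x - centre) / fwhm) ** 2)


def render_transitions(axis_ppm: np.ndarray, centres_ppm: np.ndarray,
                       areas: np.ndarray, fwhm_ppm: float) -> np.ndarray:
    """Vectorised sum of Lorentzians over the axis (chunked over lines)."""
    centres_ppm = np.asarray(centres_ppm, dtype=float)
    areas = np.asarray(areas, dtype=float)
    out = np.zeros_like(axis_ppm, dtype=float)
    if centres_ppm.size == 0:
        return out
    # keep the broadcast working set around ~4M elements
    chunk = max(1, int(4_000_000 / max(axis_ppm.size, 1)))
    for k in range(0, centres_ppm.size, chunk):
        u = 2.0 * (axis_ppm[None, :] - centres_ppm[k:k + chunk, None]) / fwhm_ppm
        np.square(u, out=u)
        u += 1.0
        np.divide(areas[k:k + chunk, None], u, out=u)
        out += u.sum(axis=0)
    out *= 2.0 / (np.pi * fwhm_ppm)
    return out


def render_spectrum(transitions: TransitionList, axis: np.ndarray,
                    linewidth: float = 1.0, concentration: float = 1.0,
                    spectrometer_freq: float | None = None,
                    name: str = "species") -> SimulatedSpectrum:
    """Render a transition list as a sum of Lorentzians on a ppm grid.

    ``linewidth`` is the FWHM in Hz (the 0.3 Hz processing line
    broadening of a real pipeline is absorbed into this effective
    width). Each transition contributes area intensity x concentration.
    """
    if linewidth <= 0:
        raise ValueError("linewidth must be > 0 (Hz FWHM)")
    freq = spectrometer_freq or transitions.spectrometer_freq_mhz
    centres = transitions.frequencies_hz / freq
    lo, hi = axis.min(), axis.max()
    if centres.size and (centres.min() < lo or centres.max() > hi):
        logger.warning("transitions outside the axis range [%g, %g] ppm are "
                       "tail-truncated", lo, hi)
    fwhm_ppm = linewidth / freq
    y = render_transitions(axis, centres, transitions.intensities * concentration,
                           fwhm_ppm)
    return SimulatedSpectrum(axis=np.asarray(axis, float).copy(), intensities=y,
                             meta={"spectrometer_freq_mhz": freq,
                                   "linewidth_hz": linewidth},
                             components={name: y.copy()})


def simulate_mixture(mixture: MixtureSpec, axis: np.ndarray,
                     linewidth: float = 1.0, spectrometer_freq: float = 80.0,
                     library: Mapping[str, Sequence[SpinSystem]] | None = None,
                     include_reference: bool = True) -> SimulatedSpectrum:
    """Noiseless spectrum of a metabolite mixture.

    Each named species is resolved through the bundled parameter library
    (a name may expand to several spin systems, e.g. glucose into its
    alpha and beta anomers with populations 0.36/0.64); per-species
    component vectors are retained on the result. The TSP reference is
    included at ``mixture.reference_concentration`` unless disabled.
    Residual water belongs to the acquisition model, not to this
    simulator.
    """
    if library is None:
        from .library import load_metabolite_library
        library = load_metabolite_library()

    axis = np.asarray(axis, dtype=float)
    fwhm_ppm = linewidth / spectrometer_freq
    components: dict[str, np.ndarray] = {}
    names_conc = list(mixture.species)
    if include_reference and mixture.reference_concentration > 0:
        names_conc.append(("tsp", mixture.reference_concentration))

    for name, conc in names_conc:
        if name not in library:
            raise KeyError(
                f"unknown species {name!r}; available: {sorted(library)}")
        y = np.zeros_like(axis)
        for system in library[name]:
            trans = compute_transitions(system, spectrometer_freq)
            y += render_transitions(axis, trans.positions_ppm,
                                    trans.intensities * conc * system.population,
                                    fwhm_ppm)
        components[name] = y

    total = sum(components.values()) if components else np.zeros_like(axis)
    return SimulatedSpectrum(
        axis=axis.copy(), intensities=np.asarray(total),
        meta={"spectrometer_freq_mhz": spectrometer_freq,
              "linewidth_hz": linewidth, "n_scans": None, "scaling": "unscaled"},
        components=components)
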