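"""Simulation-based template fitting of metabolite spectra.

Each metabolite template is its exact simulated transition list rendered
as Lorentzians and parameterised by three free quantities: a relative
intensity A_rel (>= 0, so noise-only regions default to a flat baseline
rather than a negative peak), a common full width at half maximum w
(Hz) for every line, and a global chemical-shift offset x_s (ppm). A
named species may comprise several spin systems with fixed relative
populations — glucose is fitted as its alpha+beta anomer pair at the
assumed 36:64 equilibrium with a single shared A_rel.

The fit is a bounded trust-region nonlinear least squares restricted to
a per-metabolite ppm window (high-SNR regions only); the fitted
component is then rendered over the *full* axis, so multiplets outside
the window (e.g. the lactate CH quartet near 4.1 ppm) are predicted by
the fit rather than measured. A constant in-window baseline is fitted
jointly as a fourth parameter by default — subtracting a pre-computed
region median instead would absorb part of the analyte's own Lorentzian
tails and bias A_rel low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .spinsim import SpinSystem, TransitionList, compute_transitions, \
    render_transitions
from .types import PpmInterval, Spectrum

__all__ = [
    "Template",
    "TemplateFitResult",
    "CompositeFit",
    "build_template",
    "fit_template",
    "fit_amplitude",
    "fit_mixture",
]

#: lower bound on the fitted linewidth (Hz); a Lorentzian much narrower
#: than the grid spacing is unresolvable and destabilises the Jacobian
MIN_WIDTH_HZ = 0.05


@dataclass(frozen=True)
class Template:
    """A renderable metabolite model with free (A_rel, w, x_s)."""

    species: str
    transitions: tuple[TransitionList, ...]
    populations: tuple[float, ...]
    spectrometer_freq: float

    def render(self, axis: np.ndarray, a_rel: float, width_hz: float,
               shift_ppm: float) -> np.ndarray:
        """Evaluate the template at the given parameters."""
        fwhm_ppm = width_hz / self.spectrometer_freq
        y = np.zeros_like(axis, dtype=float)
        for trans, pop in zip(self.transitions, self.populations):
            y += render_transitions(axis, trans.positions_ppm + shift_ppm,
                                    trans.intensities * (a_rel * pop), fwhm_ppm)
        return y


def build_template(species: str,
                   library: Mapping[str, Sequence[SpinSystem]] | None = None,
                   spectrometer_freq: float = 80.0) -> Template:
    """Resolve a species name into a fit-ready template.

    Multi-form species keep their library populations (glucose:
    alpha 0.36 / beta 0.64) under a single shared amplitude.
    """
    if library is None:
        from .library import load_metabolite_library
        library = load_metabolite_library()
    if species not in library:
        raise KeyError(f"unknown species {species!r}; available: {sorted(library)}")
    systems = library[species]
    return Template(
        species=species,
        transitions=tuple(compute_transitions(s, spectrometer_freq)
                          for s in systems),
        populations=tuple(s.population for s in systems),
        spectrometer_freq=spectrometer_freq,
    )


@dataclass
class TemplateFitResult:
    species: str
    a_rel: float
    width_hz: float
    shift_ppm: float
    covariance: np.ndarray  # order (A_rel, w, x_s[, baseline])
    rmse: float  # residual RMSE inside the fit region
    component: np.ndarray  # fitted spectrum over the full axis
    baseline: float  # fitted constant level inside the window
    success: bool
    fit_region: PpmInterval = None

    @property
    def a_rel_sd(self) -> float:
        return float(np.sqrt(max(self.covariance[0, 0], 0.0)))


def fit_template(spec: Spectrum, template: Template,
                 fit_region: PpmInterval,
                 fit_baseline: bool = True,
                 x0: tuple[float, ...] | None = None
                 ) -> TemplateFitResult:
    """Fit (A_rel, w, x_s) of one template to a spectrum within a window.

    A constant baseline inside the window is fitted jointly as a fourth
    parameter unless ``fit_baseline`` is False (then it is pinned at
    zero). A_rel is bounded below at zero; w and x_s are effectively
    unconstrained. Optimizer failures return a flagged result at the
    best iterate rather than raising.
    """
    x, y = spec.slice(fit_region)
    n_params = 4 if fit_baseline else 3
    if x.size < n_params:
        raise ValueError(
            f"fit region {fit_region} has {x.size} points, fewer than the "
            f"{n_params} free parameters")

    if x0 is None:
        b0 = float(np.median(y)) if fit_baseline else 0.0
        unit_peak = template.render(x, 1.0, 1.0, 0.0).max()
        a0 = max(float(y.max() - b0), 0.0) / unit_peak if unit_peak > 0 else 0.0
        x0 = (a0, 1.0, 0.0, b0)[:n_params]

    lo = np.array([0.0, MIN_WIDTH_HZ, -np.inf, -np.inf][:n_params])
    hi = np.full(n_params, np.inf)
    p0 = np.clip(np.asarray(x0, dtype=float), lo, hi)

    def residuals(p):
        base = p[3] if fit_baseline else 0.0
        return template.render(x, p[0], p[1], p[2]) + base - y

    res = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    a_rel, width, shift = (float(v) for v in res.x[:3])
    baseline = float(res.x[3]) if fit_baseline else 0.0
    dof = max(x.size - n_params, 1)
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    # covariance from the Gauss-Newton approximation J^T J
    JTJ = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(JTJ) * (2.0 * res.cost / dof)
    except np.linalg.LinAlgError:
        cov = np.full((n_params, n_params), np.nan)

    component = template.render(spec.axis, a_rel, width, shift)
    return TemplateFitResult(
        species=template.species, a_rel=a_rel, width_hz=width,
        shift_ppm=shift, covariance=cov, rmse=rmse, component=component,
        baseline=baseline, success=bool(res.success), fit_region=fit_region)


def fit_amplitude(spec: Spectrum, template: Template,
                  fit_region: PpmInterval,
                  width_hz: float, shift_ppm: float,
                  fit_baseline: bool = True) -> TemplateFitResult:
    """Linear amplitude-only fit with the lineshape parameters held fixed.

    With width and shift frozen the model is linear in (A_rel, baseline),
    so this is an ordinary least-squares solve. Freezing the shape on a
    high-SNR spectrum and refitting only the amplitude elsewhere avoids
    the variance the free nonlinear parameters add at low SNR. A_rel is
    clipped at zero to match the nonlinear fit's bound.
    """
    x, y = spec.slice(fit_region)
    n_params = 2 if fit_baseline else 1
    if x.size < n_params:
        raise ValueError(
            f"fit region {fit_region} has {x.size} points, fewer than the "
            f"{n_params} free parameters")
    t = template.render(x, 1.0, width_hz, shift_ppm)
    design = np.column_stack([t, np.ones_like(t)]) if fit_baseline \
        else t[:, None]
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    a_rel = float(max(coef[0], 0.0))
    baseline = float(coef[1]) if fit_baseline else 0.0
    resid = design @ coef - y
    dof = max(x.size - n_params, 1)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    try:
        cov_lin = np.linalg.inv(design.T @ design) \
            * (resid @ resid / dof)
    except np.linalg.LinAlgError:
        cov_lin = np.full((n_params, n_params), np.nan)
    # embed in the (A_rel, w, x_s[, baseline]) layout with frozen rows zero
    cov = np.zeros((4, 4)) if fit_baseline else np.zeros((3, 3))
    cov[0, 0] = cov_lin[0, 0]
    if fit_baseline:
        cov[0, 3] = cov[3, 0] = cov_lin[0, 1]
        cov[3, 3] = cov_lin[1, 1]
    component = template.render(spec.axis, a_rel, width_hz, shift_ppm)
    return TemplateFitResult(
        species=template.species, a_rel=a_rel, width_hz=float(width_hz),
        shift_ppm=float(shift_ppm), covariance=cov, rmse=rmse,
        component=component, baseline=baseline, success=True,
        fit_region=fit_region)


@dataclass
class CompositeFit:
    """Sum of independent per-species template fits."""

    fits: dict[str, TemplateFitResult]
    composite: np.ndarray  # pointwise sum of fitted components
    axis: np.ndarray
    residual_rmse: float  # vs the input spectrum over the full axis

    def component(self, species: str) -> np.ndarray:
        return self.fits[species].component


def fit_mixture(spec: Spectrum, templates: Sequence[Template],
                regions: Mapping[str, PpmInterval],
                fit_baseline: bool = True) -> CompositeFit:
    """Independent per-species fits summed into a composite model.

    Each species is fitted only inside its own region; the composite is
    the pointwise sum of all fitted full-axis components.
    """
    fits: dict[str, TemplateFitResult] = {}
    for tpl in templates:
        if tpl.species not in regions:
            raise KeyError(f"no fit region supplied for species {tpl.species!r}")
        try:
            fits[tpl.species] = fit_template(spec, tpl, regions[tpl.species],
                                             fit_baseline=fit_baseline)
        except ValueError as exc:
            raise ValueError(f"{tpl.species}: {exc}") from exc
    composite = np.sum([f.component for f in fits.values()], axis=0) \
        if fits else np.zeros_like(spec.axis)
    rmse = float(np.sqrt(np.mean((spec.intensities - composite) ** 2)))
    return CompositeFit(fits=fits, composite=composite, axis=spec.axis.copy(),
                        residual_rmse=rmse)
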