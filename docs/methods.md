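# Methods

This document defines the physical model, the estimators, the default
parameters (with units and rationale) and the known limitations of
`lfnmr`. Everything here is implemented in the package and exercised by
the test suite; no empirical claims are made beyond what the code
computes.

## 1. Spin simulation (`lfnmr.spinsim`)

### Hamiltonian

Each metabolite is a system of n spin-½ nuclei with chemical shifts
δᵢ (ppm) and scalar couplings J_ij (Hz). In the rotating frame the
isotropic Hamiltonian (in Hz) is

    H/h = Σᵢ νᵢ Iz,ᵢ + Σ_{i<j} J_ij (Iᵢ·Iⱼ),   νᵢ = δᵢ · f_spec

with f_spec the spectrometer frequency in MHz (default 80.0). The full
Iᵢ·Iⱼ product is kept, so strong coupling is exact: at 80 MHz many
metabolite multiplets have Δν comparable to J and the familiar
first-order patterns roof, shift and grow combination lines.

The spin set is partitioned into coupled clusters (union-find over the
J matrix); each cluster's H is built from Kronecker products of Pauli
operators and diagonalized densely (`numpy.linalg.eigh`). Cluster size
is capped at 10 coupled spins (2¹⁰ Hamiltonian) and 16 spins total per
system — sufficient for the bundled metabolites, with a clear error
when exceeded.

### Transitions

For eigenstates |i⟩, |f⟩ the single-quantum transition weight is

    w_fi = |⟨f| I₋ |i⟩|² / 2^(n−1),   frequency E_i − E_f  (Hz)

The 2^(n−1) normalisation makes the weights of one spin sum to exactly
1, so a species' total transition intensity equals its proton count —
verified against an independent brute-force implementation and by a
property test over random coupling matrices. Transitions degenerate to
within 10⁻⁶ Hz are merged at their weighted centroid; weights below
10⁻⁸ of the total are pruned.

### Rendering

Each transition becomes a Lorentzian of area = weight × concentration
(mmol/L): one proton at 1 mmol/L has unit area on the ppm axis. The
default full width at half maximum is 1.0 Hz (0.0125 ppm at 80 MHz), a
typical benchtop shimmed linewidth. The canonical axis runs 10.0 →
−2.5 ppm at 6.1487·10⁻⁴ ppm/point (≈20 330 points), decreasing ppm as
is conventional for NMR display.

### Bundled spin systems

`lfnmr/data/metabolites.json` carries literature shift/J sets
(GISSMO/HMDB-derived) for α-/β-glucose (7 coupled spins each, populations
0.36/0.64 under the shared parent name `glucose`), lactate (CH + CH₃,
J = 6.95 Hz), citrate (two independent AB pairs, δ 2.672/2.539 ppm,
J = −15.4 Hz) and TSP (9 equivalent protons at 0.00 ppm).

## 2. Acquisition model (`lfnmr.acquisition`)

A synthetic acquisition is:

    S(δ) = g · p · [ M(δ − Δ) + a_w · W(δ − Δ) ] + ε,  ε ~ N(0, σ²/n_scans)

| symbol | meaning | default | rationale |
|--------|---------|---------|-----------|
| M | noiseless metabolite + TSP spectrum | — | section 1 above |
| W | residual water Lorentzian at 4.8 ppm | height 200× tallest metabolite peak, FWHM 5 Hz | dominant benchtop artefact |
| p | per-scan signal factor | zg 1.0, zg30 0.5, wet 0.95 | pulse-angle projection |
| a_w | water attenuation | zg/zg30 1.0, wet 10⁻³ | solvent suppression |
| g | receiver gain factor | zg/zg30 1.0, wet 4.0 | gain headroom freed by suppression |
| Δ | global shift jitter | N(0, 0.002 ppm) per acquisition | field drift between runs |
| σ | 1-scan noise s.d. per point | 16.5 | calibrated once so the 1-scan zg30 glucose integral-SNR of the mixed sample ≈ 4.3 (study-condition anchor); not revisited |
| per-scan duration | s | zg 15, zg30 5, wet 5 | repetition-time bookkeeping |

Scan averaging is drawn as a single N(0, σ/√n) vector — statistically
identical to averaging n independent scans. All randomness flows through
`numpy.random.default_rng(seed)`; `acquisition_series` derives child
seeds (< 2³¹) from a `SeedSequence` so series members are independent
but reproducible.

The standard mixed sample is glucose 10, lactate 2, citrate 0.2 mmol/L
with TSP at 0.1 mmol/L.

## 3. Preprocessing (`lfnmr.preprocess`)

- **Reference fit:** Lorentzian + constant fitted to the TSP window
  (−0.05..0.05 ppm, ≥10 points). Results are flagged (not raised) when
  the optimizer fails or the fitted height is < 3× the residual RMSE.
- **Alignment:** the spectrum is re-interpolated so the fitted TSP
  centre sits at 0.00 ppm; shifts above 0.1 ppm are rejected as a sanity
  bound. Alignment is idempotent to interpolation error.
- **Scaling:** intensities are multiplied by (reference TSP area /
  fitted TSP area), equalising the internal standard across spectra.

## 4. Metrics (`lfnmr.metrics`)

Three SNR conventions on disjoint signal/noise regions (default noise
region −2..−1 ppm, deliberately signal-free):

1. `integral` — mean |I| over the signal region / mean |I| over the
   noise region. Conservative: wide windows dilute it.
2. `topspin_like` — max |I| / (2 · noise RMS about the mean).
3. `vnmrj_like` — max |I| / noise RMS. By construction
   vnmrj/topspin = 2 exactly.

LOD/LOQ crossings report the first scan count whose SNR reaches 3
(detection) or 10 (quantification), or None.

**Metabolite bounds** come from the normalised cumulative intensity
integrated high→low ppm: the 2σ bounds are its 0.023/0.977 crossings
(linear interpolation), the centre its 0.5 crossing. The quantile
construction guarantees ≈95.4% of the simulated intensity lies inside
the 2σ interval. The default windows (glucose 3.19–3.98, lactate
1.17–1.50, citrate 2.37–2.82 ppm) follow this construction at 80 MHz.
Note: the simulated glucose 2σ upper edge sits ≈0.06 ppm below 3.98
because strong H6/H6′ coupling suppresses the outermost lines at 80 MHz.

## 5. Template fitting (`lfnmr.template_fit`)

A species template is its exact transition list with free parameters
A_rel (amplitude ≥ 0, in profile-scaled concentration units), shared
linewidth w (Hz, ≥ 0.05) and global shift x_s (ppm), plus a constant
baseline fitted jointly by default. The fit is bounded trust-region
least squares inside a per-metabolite window; the fitted component is
rendered over the full axis, so out-of-window multiplets are predicted.
Glucose anomers share one A_rel at fixed 36:64 populations. Parameter
covariance is the Gauss–Newton (JᵀJ)⁻¹ estimate scaled by the residual
variance.

The baseline is a *fitted* parameter rather than a pre-subtracted region
median: the analyte's own Lorentzian tails dominate the median of a
narrow window, and subtracting it biases A_rel low by ~15% in realistic
windows. With the joint baseline, noiseless recovery is exact to
optimizer precision (≤10⁻⁴ relative).

`fit_amplitude` freezes (w, x_s) and solves the then-linear problem for
(A_rel, baseline): at low SNR the free nonlinear shape parameters add
variance (measured on 1-scan lactate: 6.6% relative amplitude spread for
the 4-parameter fit vs 4.6% amplitude-only), so series analyses estimate
the shape once on the highest-scan-count spectrum and amplitude-fit the
rest.

## 6. Ratios and scaling (`lfnmr.scaling`)

- **Signal ratio** R_XY = Σ I(X window) / Σ I(Y window) with signed
  sums; uncertainty propagates noise RMS × √(points) per window. By
  construction R_XY·R_YX = 1.
- **Simulation-fit ratio** uses fitted components instead of raw sums;
  relative uncertainty is sd(A_rel)/A_rel per species.
- **`ratio_series`** computes both estimators across an (aligned) scan
  series, freezing template lineshape on the highest scan count.
- **Stability** (`ratio_stability`): per-estimator std across scan
  counts and a fidelity floor — the smallest n from which the ratio
  stays within 20% (default) of the highest-scan-count reference. Under
  the water-suppressed pipeline the template-constrained citrate/glucose
  ratio varies less than raw integration on ≈90% of noise seeds.
- **Power law**: OLS of log SNR on log n_scans → SNR = A·nᴮ; ideal
  scan averaging gives B = 1/2. An optional SNR floor excludes
  noise-dominated points that flatten the apparent exponent. Rescaling
  A by a concentration factor predicts a diluted sample's series
  (signal is linear in concentration).

## 7. I/O (`lfnmr.io`)

CSV (`ppm,intensity`, full double precision) and a deliberately small
JCAMP-DX subset: AFFN `##XYDATA=(X++(Y..Y))` (plus the simple NTUPLES
single-table dialect on read). Compressed ordinate forms (SQZ/DIF/DUP)
are not supported; files written by the package are always AFFN. All
reads normalise to decreasing-ppm orientation. Run configurations are
YAML with validated species names and ppm windows.

## 8. Numerical choices

- Dense `eigh` per cluster: exact, and cheap at ≤2¹⁰ dimensions.
- Lorentzian rendering is chunked (~4·10⁶ elements per broadcast) to
  bound memory; a full mixed-sample render takes well under a second.
- Degenerate-transition merge tolerance 10⁻⁶ Hz; intensity prune floor
  10⁻⁸ of the total (both far below rendering resolution).
- Alignment uses linear re-interpolation; its distortion of a 1 Hz line
  is below 1% of peak height for sub-0.01 ppm shifts.
- All stochastic code takes explicit seeds; derived seeds stay < 2³¹.

## 9. What the generator does not emulate

- Free-induction decay, apodization and Fourier processing: spectra are
  generated directly in the frequency domain with Lorentzian shapes, so
  line-broadening/phase/apodization artefacts are out of scope.
- Correlated or 1/f baseline noise, phase errors and baseline roll:
  noise is i.i.d. Gaussian per point. Consequently windowed integration
  is more stable here than on real instruments — where baseline
  artefacts penalise integration further, favouring template fits even
  more strongly.
- Temperature/pH-dependent shift changes (only a global jitter is
  modelled, not per-metabolite drift), radiation damping, and T₁/T₂
  relaxation effects on repetition timing.
- Quantitative water-peak shape: residual water is a single broad
  Lorentzian with profile-dependent attenuation.

These are modelling simplifications, not measurement claims; numbers
produced by the package characterise the model defined above.
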