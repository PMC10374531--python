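# Methods

This note documents the models, algorithms, defaults and known limitations
of the `ecmech` pipeline, in the order the data flow runs.

## Units

Lengths (piezo z, indentation δ, deflection d, tip radius R) in nm; voltage
in V; sensitivity s in nm/V; spring constant k in N/m (numerically equal to
nN/nm); force in nN; Young's modulus E in Pa. With these units the Hertz
prefactor c = F/δ^{3/2} is in nN/nm^{3/2} and nN/nm² ≡ GPa, so a single 10⁹
factor converts prefactors to Pa.

## Forward model (synthetic data)

A synthetic approach curve solves, at every piezo position z past the
contact point z_c, the force balance between the cantilever and the
spherical Hertz contact:

    k·d = (4/3)·E/(1−ν²)·√R·δ^{3/2},   δ = (z − z_c) − d.

Written in the indentation u = δ, the residual f(u) = c·u^{3/2} + k·u − k·(z−z_c)
is strictly increasing and convex on [0, z−z_c], so Newton started at the
upper bracket converges monotonically; iteration stops at |f| < 10⁻⁶ nN.
The voltage channel is d/s plus i.i.d. Gaussian noise (default 2 mV) and an
optional linear baseline tilt; noise is applied to the *voltage* channel so
force and indentation are perturbed through the same physical path, as in
the instrument. The ramp is truncated when k·d exceeds the load trigger
(default 1000 nN), which reproduces the several-µm maximum indentations of
stiff-lever tissue measurements. Only the approach segment is generated:
the analysis uses approach curves and treats tip–sample adhesion as
negligible, so retraction carries no information here.

Defaults (each a package choice where the measurement protocol leaves the
value open): ramp 15 µm / 8192 points; lever k = 5 N/m; probe radius
R = 10 µm; sensitivity s = 50 nm/V; contact at ~20 % of the ramp with ±5 %
jitter per cell; 11×11 grids (121 curves per force volume); normal-tissue
median modulus 10 kPa, which with the 1000 nN trigger gives ~5–7 µm maximum
indentations.

Ground-truth modulus fields are log-normal mixtures: each cell's modulus is
`median · 10^(σ·N(0,1))` for its assigned mode. The default within-FV width
is σ_log10 = 0.15 — a single region of interest of soft tissue shows a
roughly half-decade unimodal spread; the broader, clearly multimodal
distributions seen when pooling across regions are modelled with explicit
mixture modes (optionally spatially correlated by thresholding a
Gaussian-smoothed latent field, so stiff/soft patches form), not by
inflating the single-mode width.

What the generator does *not* emulate: viscoelastic (rate-dependent)
response, thermal drift, adhesion/retraction hysteresis, tip contamination,
finite sample thickness, and instrument artefacts beyond white voltage
noise and linear baseline tilt. Passing tests therefore demonstrate
correctness of the inverse pipeline under the Hertzian, elastic,
white-noise model — not robustness to every real-world artefact.

## Contact-point detection

A deterministic two-stage grid search per curve:

1. **Coarse two-segment split.** For every candidate index in [5 %, 95 %] of
   the ramp: a straight-line fit to the voltage before the candidate
   (baseline) plus a straight-line fit to y = sign(g)·|g|^{2/3} after it
   (g = baseline-corrected voltage; for spherical contact F^{2/3} ∝ δ).
   Both SSE profiles come from prefix/suffix cumulative sums, so the scan is
   O(n). The candidate minimizing the summed SSE wins; ties go to the
   smallest index. A candidate needs a positive post-contact slope, and the
   curve's tail signal must exceed 8 standard deviations of the baseline
   noise (per-point, scaled by the tail length) — otherwise the curve never
   contacts and a contact-not-found error is raised rather than latching
   onto a noise fluctuation.
2. **Power-law refinement.** Around the coarse index, candidates are
   re-scored by fitting g = a·u^{3/2} with u = x − x_candidate, where
   x = z − s·g is the tip–sample distance (this removes the curvature that
   finite lever compliance introduces when regressing against z). The fit is
   linear in a, so each candidate's SSE is closed-form. Fitting the
   *untransformed* signal keeps the additive voltage noise unbiased — the
   2/3-power transform of the coarse stage is nonlinear in the noise and
   would bias the estimate late. The refinement window is 512 points and the
   neighbourhood ±96 candidates, re-centred up to 4 times because soft
   samples bury the contact under the noise floor for >100 ramp steps.

Rigid (stiff-substrate) contact is a degenerate case: x is constant past
contact, so the power law has no lever arm. When the post-coarse x-span
collapses (< 5 % of the z-span) the split is instead refined with a
linear–linear model on the raw voltage, which is exact in the rigid limit.

Measured behaviour at the default noise (2 mV), 10 kPa sample: median
|z_c error| ≈ 12 nm, mean error within one ramp step (≈1.8 nm) — i.e.
unbiased under symmetric noise. Noise-free, the detected contact is within
one ramp step of truth across 0.5–100 kPa.

## Rescaling and quality control

Baseline: straight line over the first 80 % of pre-contact points (offset
and tilt subtracted). Then d = s·(V − baseline), F = k·d,
δ = (z − z_c) − d; only δ ≥ 0 is retained, with no interpolation (retained
points are a subset of raw samples). A curve is unusable (empty-contact
error) only when it has neither positive indentation nor any contact force —
the force clause matters because an ideal rigid-contact curve legitimately
has δ = 0 throughout its contact segment while the force grows.

Per-curve quality control (thresholds are package decisions; the protocols
this mirrors do not state theirs): discard when maximum indentation
< 500 nm (too shallow to average the ECM network response) or fit R² < 0.8.
Discards are logged with reasons, counted in the QC report, and left as
missing map cells — never silently dropped.

## Hertz fit

The one-parameter model F = c·δ^{3/2} is fitted by closed-form least squares
on the 20–80 % band of the indentation axis (the first 20 % is dominated by
superficial non-crosslinked fibres and surface roughness; the window is
measured on the indentation axis relative to δ_max). c = Σ F·δ^{3/2} / Σ δ³,
E = (3/4)·c·(1−ν²)/√R. The closed form is deterministic — no initial values
or convergence tolerances — and is cross-checked in the test suite against
iterative nonlinear least squares (agreement < 10⁻⁶ relative). ν defaults
to 0.5 (incompressible).

δ_max > R raises a validity flag but keeps the fit: for micrometre-scale
spherical indenters the Hertz expression stays accurate up to δ ≈ R. No
finite-thickness (bottom-effect) correction is applied; the intended
specimens (100–200 µm sections) are much thicker than the contact radius at
maximum indentation.

## Per-FV median and condition statistics

Under the log-normal hypothesis the per-FV median modulus is 10^centre of a
Gaussian least-squares fit to the log₁₀E histogram (Freedman–Diaconis bins,
at least 8; fit initialized at the sample mean/SD; computed on mean-centred
log values, which makes the estimate scale-equivariant to numerical
precision). If the fit fails, its centre leaves the data range, or the fit
R² is below 0.9, the sample median is used instead; the R² branch also sets
a multimodality flag so a clearly multimodal distribution is never silently
summarized by a single-mode fit. At force-volume sizes of 100–225 curves
the histogram is noisy enough that this flag fires on a substantial
fraction of genuinely unimodal FVs — it is deliberately conservative, and
the sample-median fallback it triggers is the robust choice either way.

Condition level: mean of the per-FV medians ± SEM (SD/√n_FV; undefined and
reported missing with a single FV). Calibration uncertainty is propagated
by Monte Carlo: per replicate, k′ ~ N(k, 0.10·k) and s′ ~ N(s, 0.05·s)
(defaults; non-positive draws redrawn), rescale+fit re-run on a stratified
subsample (9 evenly-spaced fitted cells per FV, reusing the found contact
points), replicate statistic = mean over FVs of the per-FV sample median
(the subsample is below the Gaussian-fit minimum of 20 values). The
returned relative error SD/mean is added in quadrature to the SEM.

Because the fitted E is exactly proportional to k, a 10 % spring-constant
uncertainty alone necessarily yields ≈10 % relative error from this
procedure (the package measures 0.10 ± 0.01 against this analytic limit).
A substantially smaller combined figure can only arise from additional
averaging over probes/sessions whose calibrations are independent, which is
outside this single-calibration model; the procedure here reports what the
stated inputs imply.

## Patient comparison and cohort associations

Relative stiffening = (E_neo − E_norm)/E_norm from the condition
mean-medians. Significance: two-tailed Welch (unequal-variance) t-test on
the two sets of per-FV medians at p < 0.05 — medians, not pooled curves,
because curves within an FV are spatially correlated and would inflate the
effective n. Degenerate zero-variance comparisons use the convention
t = 0, p = 1 for identical groups. The type-I error of this construction is
calibrated: on null cohorts it rejects at 0.050 ± 0.01 (measured over
10 000 replicates).

Cohort associations: Pearson r (two-sided p) of normal-tissue modulus and
of stiffening against age; Welch t-tests of stiffening for chemotherapy,
sex, KRAS/BRAF mutation (status "ND" drops a patient from this contrast
only) and grade G2 vs G3; histology reported descriptively. Raw p-values
are reported alongside a Holm-adjusted column — the raw values mirror how
such exploratory panels are usually read, the adjusted column makes the
multiplicity explicit. An exclusion list removes patients (e.g. a rare
histology outlier) from association analyses while keeping them in
per-patient summaries.

## Problem sizes used in validation

The validation suite runs at the following scales, chosen to exercise the
estimators at realistic instrument dimensions while completing on one CPU
in minutes: noise-free recovery over a 5×2×2 grid of (E, R, k); 100 curves
for the closed-form/NLS cross-check; 1000 seeds for noisy sensitivity
recovery; 10⁴ samples for median extraction; 10 000 reduced-size replicates
(5 FVs × 25 moduli per side) for type-I calibration; one full-scale patient
(2 conditions × 5 FVs × 121 curves at 2 mV noise) for stiffening recovery
plus 10 full-scale null patients for specificity; 2000 Monte Carlo
replicates for the calibration-error limit. Unit tests use smaller Monte
Carlo sizes (e.g. 300 seeds for contact-point statistics) for the same
properties.

## Known limitations

* Elastic, non-adhesive spherical contact only: no viscoelastic or adhesive
  (JKR/DMT) models, no conical/pyramidal tips.
* The contact-point algorithm is validated for internal consistency against
  the package's own forward model; equivalence with any particular
  published MATLAB implementation cannot be asserted.
* Spring-constant and sensitivity calibration are inputs (with
  uncertainties); thermal-noise k calibration and contactless sensitivity
  procedures are out of scope.
* The synthetic cohort draws FV medians from the same per-condition
  distribution (no extra between-location variance component); real tissue
  adds spatial heterogeneity between regions, which would widen per-patient
  errors relative to the synthetic case.
* Vendor instrument file formats are not parsed; data enter through the
  package's open HDF5/JSON/TSV container (an import stub documents the
  mapping).
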