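# Methods

## Signal model and conventions

The voxel signal is modelled as a two-compartment biexponential,
S(b) = S0·[f·e^(−b·D*) + (1−f)·e^(−b·D)], with b in s/mm² and D, D* in
mm²/s (typical tissue D ≈ 1×10⁻³ mm²/s). D* is the *total* pseudo-diffusion
coefficient of the fast compartment; the blood-water diffusivity is not
modelled as a separate additive term. Model assumptions: both compartments
mono-exponential (no kurtosis — valid at the moderate b-ranges of the organ
tiers), no exchange between compartments, isotropic diffusion (direction
volumes are trace-combined before fitting), and nominal b-values taken as
true b-values (cross-terms from imaging gradients are out of scope).

SNR is defined at b = 0: σ = S0/SNR, constant across b. Gaussian noise adds
ε ~ N(0, σ²); Rician noise is the magnitude of a complex signal with
independent N(0, σ²) on both channels, the distribution of
magnitude-reconstructed MRI, with the familiar positive floor at low SNR
(E[magnitude] ≥ signal, checked against the closed-form Rice mean). All
randomness flows through explicitly seeded `numpy` generators; nothing uses
global state.

The T2 correction of f inverts two-compartment relaxation weighting,
f = f_meas·e₂ / (f_meas·e₂ + (1−f_meas)·e₁) with e₁ = exp(−TE/T2_blood),
e₂ = exp(−TE/T2_tissue). The relaxation-weighting form itself is a modelling
choice (only the concept, not a formula, is standardised in the field); it
is exactly the inverse of the forward weighting, verified to 1e−10 on a
(f, TE, T2) grid.

## Fitting

**High-b step (WLLS).** ln S is regressed on b with weights equal to squared
model-predicted signals — the first-order correct weighting for
log-transformed additive noise. The first pass weights by the observed
signals; each further iteration re-weights from the fitted values. Default 2
iterations (initial + one refresh); more change little on 6-point designs.
Non-positive samples are excluded with a warning because the log is
undefined there.

**Segmented fit.** Step 1 runs the WLLS on b ≥ b_threshold (200 s/mm²; 300
for brain) giving D and the b = 0 intercept; f = 1 − intercept / mean
measured b = 0 signal — the *measured* mean, not a fitted S0, so repeated
b = 0 volumes are averaged first. Step 2 fits the full biexponential over
all b with D frozen; the default `segmented_fix_df` variant also freezes f
and S0 (slightly more consistent in community practice), leaving D* as the
single free parameter, initialised at 10·D. The `segmented_refit_f` variant
re-solves f jointly with D* and S0 (S0 refit is our choice; fixing it is
equally defensible). Negative f estimates are clipped to 0 and flagged, and
D* is then reported undefined rather than fabricated.

Because a finite pseudo-diffusion component survives above the threshold,
the segmented estimator has a small positive bias in D and negative bias in
f on clean biexponential input; the bias shrinks monotonically as
D*·b_threshold grows. Both properties are asserted in tests across all organ
presets.

**Full NLLS.** Bounded trust-region least squares over (S0, f, D, D*) with
the analytic Jacobian, initialised from the segmented fit unless an explicit
guess is given. Default bounds: f ∈ [0, 1], D ∈ [10⁻⁵, 5×10⁻³],
D* ∈ [max(10⁻⁵, D), 0.5] mm²/s, S0 ∈ (0, 2·max signal] — generous around
every organ prior. Tolerances are set to machine-level (1e−14) so noiseless
round-trips recover parameters to ≪0.1%.

**Voxelwise fitting.** Direction volumes at equal b are collapsed by
geometric mean (arithmetic mean of log-signals — consistent with the
log-linear machinery); b = 0 repeats stay separate samples. Voxels with any
non-positive collapsed signal are skipped and flagged, not clipped. Maps
carry a missing-value code (−1) and an integer flag map.

## Organ presets and priors

Presets encode the nested b-value tiers (3-value abbreviated ⊂ 6-value
minimal ⊆ advanced, compared as multisets so repeated b = 0 counts),
b_threshold, TR/averages/direction minima, resolution and slice-thickness
ranges and fat-suppression expectations. Two encodings are deliberately
config-overridable because published recommendation tables merge cells
ambiguously: TR minima (brain/muscle/breast 4 s, kidney/liver/pancreas 3 s)
and the resolution/slice ranges. Fat suppression is checked at warn level
only — it cannot affect fitting.

The packaged per-organ (mean, SD) priors for f, D, D* are **reconstructed
placeholders** assembled from organ-level IVIM meta-analyses and reviews,
not a verbatim copy of any single table; users can override the YAML with
their own values. Two pins anchor the reconstruction: the brain mean D* is
fixed at 10.9×10⁻³ mm²/s so the factor-20 suppression b-value ln 20/D*
equals the conventional 275 s/mm² brain threshold, and the kidney prior
(f = 0.18 ± 0.06, D = 1.7 ± 0.3 ×10⁻³, D* = 30 ± 15 ×10⁻³ mm²/s) is the
literature-plausible choice whose CRLB-optimal 6-value design, with the
abbreviated tier fixed, lands closest to the published CRLB-derived kidney
set (0, 0, 30, 150, 200, 800). For every organ the implied suppression
b-value stays at or below the preset b_threshold (tested).

## CRLB design

Gaussian-noise Fisher information over the free parameters (S0, f, D, D*):
I = σ⁻² Σ_b ∇S ∇Sᵀ, repeats additive. S0 is kept free as a nuisance
parameter (a 4×4 matrix) — treating it as known would understate the other
uncertainties. Structural singularities (f = 0, D = D*, fewer than 4
distinct b) are rejected with named errors. CRLB σ are the square roots of
the inverse-information diagonal and scale exactly as 1/SNR; supersets of
b-values never increase any σ (both tested to machine precision).

The design cost is σ_D/D + σ_D*/D* + σ_f — absolute for f so the metric
does not diverge as f → 0 — averaged arithmetically over a 3-point-per-
parameter Cartesian grid (mean − SD, mean, mean + SD; 27 points; resolution
and aggregation configurable). Grid f values are floored at 0.01 to keep
every point non-singular. The optimizer enumerates all combinations with
repetition of the free slots over a 0…1000 s/mm² grid in steps of 10
(repeated b = 0 allowed), fully vectorised (chunked batches of 4×4
inversions; the default kidney problem — 176,851 candidate triples × 27
prior points — runs in a few seconds); ties break to the lexicographically
smallest sorted multiset, making the search deterministic and
enumeration-order independent.

A caution on attainability: the CRLB is a *lower bound*. At SNR 100 the
bound is met within ~10% by full NLLS only where the perfusion compartment
is well identified (effective perfusion SNR ≈ f·SNR). For the liver preset
(f = 0.24) Monte Carlo dispersion matches the bound; for low-f organs such
as brain (f = 0.05) the D* likelihood is nearly flat and empirical scatter
exceeds the bound many-fold at that SNR. Design *comparisons* between
b-sets remain informative there, but the absolute σ values should not be
read as achievable errors at low f·SNR.

## Monte Carlo planner

Each condition draws n noisy realizations, refits, and summarises relative
bias b_x, relative dispersion s_x and total relative error
e_x = sqrt(b_x² + s_x²) (root-sum-square is the default, pluggable metric).
Non-converged replicates — and segmented fits whose f clipped to zero,
leaving D* undefined — are excluded from the moments but counted; a failure
rate above 50% marks the result unreliable. The SNR scan resets the same
substream at every SNR level (common random numbers) so the error-vs-SNR
curve is monotone up to fit nonlinearity; the minimal-SNR answer is the
smallest grid point meeting the target, with no interpolation. Default
1,000 replicates per condition (desk scale: ±~2% on a dispersion estimate);
larger runs are a flag away.

## Phantoms and reporting

Phantoms draw per-voxel (f, D, D*) from the organ prior with SDs scaled by
0.5 (within-organ spread is narrower than the between-study literature
spread) truncated to physical ranges, evaluate the forward model on the
tier's b-set (optionally 3 direction volumes per b > 0), and add seeded
Gaussian or Rician noise; background voxels are pure noise. What the
phantom does *not* emulate: anatomy, partial volume, motion, eddy currents,
EPI distortion, spatially correlated noise, T1/T2 relaxation differences
across compartments. Passing end-to-end tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
real-world artefacts — those are the province of the (out-of-scope)
pre-processing steps.

ROI statistics report mean, SD, median and IQR per label, quantiles by
linear interpolation (fixed so IQRs are comparable across software), over
non-flagged voxels only; empty labels are omitted with a warning.
Statistics are invariant to voxel enumeration order (tested).

## Validation problem sizes

The test suite runs noiseless round-trips and bias-direction checks on all
six organ presets; CRLB-vs-Monte-Carlo agreement at SNR 100 with 10,000
Gaussian replicates per organ (and 4,000 at SNR 200 for the liver-regime
unit test); the D < f < D* error ordering at SNR 25 with 1,000 replicates
per organ; and a 500-voxel SNR-50 Rician kidney phantom fitted voxelwise
(median D within 5%, median f within 15% of truth). The acceptance script
uses 2,000 replicates for the CRLB-Monte-Carlo check and 1,000 for the
error ordering, and finishes in well under a minute on one core.

## Known limitations

* The CRLB machinery assumes Gaussian noise; a Rician-likelihood bound is
  not implemented. At SNR ≥ ~50 the distinction is negligible for these
  designs (tested by comparing Gaussian and Rician Monte Carlo).
* The packaged priors are reconstructed literature summaries (see above);
  studies wanting exact reproduction of a specific prior table should
  override the YAML.
* b-value corrections for imaging gradients, motion/distortion correction,
  denoising and signal-void detection are intentionally out of scope; the
  series container only offers a volume-exclusion hook.
* T1 correction of f is not provided, only T2 correction at a known TE.
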