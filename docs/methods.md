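# Methods

This note documents the models implemented in `tumorio`, the choices
made where the published description leaves the design open, and what
the synthetic-data generator does and does not emulate.

## Expression signatures

A signature score on a profile E (log₁₀(TPM + 1)) is the weighted mean
of the positively weighted genes minus the weighted mean of the
negatively weighted genes.  Both denominators use |wᵢ|, so each term is
a convex combination of expression values.  Two consequences are used as
test invariants: the score is invariant to adding a constant to every
Eᵢ when both sign groups are non-empty, and it is bounded by
(min positive E − max negative E, max positive E − min negative E).  A
formula that divided the negative group by the signed weight sum would
flip the sign of the subtracted term; the convex-combination reading is
implemented as the evident intent of "positive mean minus negative
mean" and is the documented convention throughout.

The total metabolic-activity score is the sum of the primary and
secondary metabolism sub-scores.  PD-L1 is mapped to the gene symbol
CD274 (configurable); a cell is PD-L1-positive iff TPM > 1, strictly.

**Pseudo-TPM normalization.**  Microarray intensities are made
comparable to RNA-seq by per-gene affine maps in log space sending the
observed (0%, 90%) quantiles onto reference quantiles.  The 0% quantile
is read as the per-gene minimum; quantiles are empirical with linear
interpolation.  The map is increasing, hence rank-preserving, and
idempotent against the same reference.  A zero-spread gene has no scale
information and is mapped to the constant reference q0 with a warning.

**Correlations** between PD-L1 and signature scores are pooled Pearson
correlations across cells, both variables in log₁₀(TPM + 1) space (raw
TPM on the PD-L1 axis is available behind a flag; per-patient
correlation is a trivial restriction of the pooled call).

## Biophysical feature maps

The proprietary simulation engine behind the original feature maps is
unpublished.  This package replaces its glucose model with the simplest
reaction–diffusion model that has a closed-form oracle: steady-state
linear uptake,

    D ∇²c = k · m(class) · c,

with Dirichlet c = 1 on vasculature voxels, no-flux (mirror) boundaries,
and per-class uptake multipliers m (defaults: tumor 1.0, gland/skin/
chest 0.3, fat 0.1, air and vessels 0).  Michaelis–Menten uptake would
be a straightforward extension but has no analytic reference solution.

Discretization is the 7-point stencil on the voxel grid; the resulting
symmetric positive-definite system is solved by Jacobi-preconditioned
conjugate gradients to relative residual 1e-8 (iteration cap 1e5;
non-convergence raises with the residual).  The discrete maximum
principle bounds all values in [0, 1].  On a pseudo-1D slab with a
vessel plane at x = 0 the exact profile is exp(−x√(k/D)); the solver is
required to track it within 2% away from the far wall, which sets the
resolution used in the oracle tests (0.25 mm voxels — the leading
discretization error in the decay rate is ~kh²/24 per unit length).

Parameter defaults: D = 1 mm²·step⁻¹ and k = 0.25 step⁻¹, i.e. a
2 mm decay length in tumor tissue, of the order of diffusion-limited
nutrient penetration around microvasculature at MRI-scale resolution;
only the ratio k/D matters at steady state.  The glucose threshold
(default 0.2 relative units) was chosen on the spherical phantom library
so that active fractions traverse (0, 1) as tumor radius and vessel
geometry vary; it is exposed in configuration, as the published
threshold value is not stated.

The **metabolic activity map** is the nutrient field on tumor voxels at
or above the threshold, zero elsewhere; its summary feature is the
fraction of tumor voxels with activity > 0 (voxel counts, not
partial-volume weighted).  The **TME** is the band of non-tumor voxels
within a Euclidean distance (default 5 mm — the published account never
quantifies "localized area surrounding the tumor") of the tumor.  The
**angiogenesis fraction** is the fraction of TME vasculature voxels with
leakiness strictly above 0.9·L_max.  L_max is a calibration constant; by
default it is taken as the 99th percentile of pooled vessel leakiness
over a reference cohort (`calibrate_leakiness_max`), since the original
calibration cohort is not available.  Leakiness itself is an *input*
field here — the biophysics that produces it in the original engine is
unpublished.  Both summary fractions are monotone non-increasing in
their thresholds, and both must be stable (< 5% drift) under halving the
voxel size on a fixed-geometry phantom.

## Scoring model

Per subtype (TNBC, HR+/HER2−), ordinary least squares regresses the
{0, 1}-coded outcome on the two features — a linear probability model,
matching the published "linear regression" description; an unpenalized
logistic fit is available behind a flag for sensitivity analysis.  Rank
deficiency is detected before fitting and the offending feature named.

The decision threshold maximizes training accuracy over a deterministic
candidate set: the midpoints of adjacent sorted unique training scores,
bracketed by the lowest score (all-pCR under the ≥ rule) and a value
just above the highest (all-residual).  Ties go to the smallest
maximizer.  With a single unique score that score is the threshold.
Scores equal to the threshold classify as pCR; the published account
states no boundary convention, and ≥ is fixed here and tested.  The
published per-patient scores are threshold-consistent with the
published calls — a single cutoff per subtype (TNBC in (0.496, 0.621],
HR+/HER2− in (0.255, 0.401]) reproduces all 17 calls — and this
consistency is a fixture test; the original coefficient and threshold
values themselves were never printed.

## Trial statistics

The confusion table is oriented predicted × clinical.  The odds ratio is
(TP·TN)/(FP·FN) with the log-normal CI exp(ln OR ± z·√(ΣTP⁻¹…)); a zero
cell raises unless the Haldane–Anscombe +0.5 correction is explicitly
requested, because the formula presumes positive cells.  Proportion CIs
are exact Clopper–Pearson intervals from the Beta-quantile
characterization (lo = 0 at k = 0, hi = 1 at k = n); they are verified
against `statsmodels` (`proportion_confint(method="beta")`) as an
independent route and are conservative — simulated coverage stays above
the nominal 95% across a (p, n) grid.  Report formatting rounds
percentages to one decimal.

The virtual trial classifies each patient of an IO-naïve cohort with the
trained subtype model, reports the per-subtype predicted pCR rate with
its exact CI, and sets the observed outcome column (chemotherapy-alone
results) beside it as the control arm.  No response mechanism beyond
thresholding the score is modeled, mirroring the published design.

## Synthetic-data generator

The generator defines the study conditions for every test and for the
acceptance script; its defaults are fixed, not tuned per run.

**Expression.**  Default cohort: 8 patients × 236 cells ≈ 1.9k pooled
tumor cells, 100 genes, target correlations +0.24 (angiogenesis) and
−0.29 (metabolic activity) — the magnitudes reported for pooled
single-cell TNBC analyses — noise SD 0.30 log₁₀ units, and patient-level
PD-L1 dropout probability 0.25 (two of eight patients with no PD-L1+
cell).  Construction: per cell, a standard-normal PD-L1 latent z_p and
signature latents z_m, z_a tied to it in a chain (corr(z_m, z_a) =
ρ_m·ρ_a, the conditional-independence structure, which keeps the
correlation matrix positive definite for any |ρ| < 1).  Observables are
affine maps in log₁₀(TPM + 1) space censored at 0: PD-L1 has mean 0.15
and SD 0.60, giving ≈ 40% of cells above the TPM > 1 cutoff and about
two orders of magnitude of spread among positive cells; each signature
gene adds a fixed loading of 0.5·z on a per-gene baseline drawn once
from U(0.5, 2.5).  The latent correlations are *inflated analytically*
so the observable score-vs-PD-L1 Pearson r hits the target: the
censoring attenuation corr(max(μ+σZ, 0), Z) is computed by quadrature
and the noise attenuation b/√(b² + σ²/n_genes) in closed form.  The
calibration is exact to well under 0.01 at large n (checked at
n = 50,000 during development of the tests at n = 2,000, whose
tolerance is the Fisher-z sampling band).  Unreachable targets (|ρ|
needed > 0.99) raise.  A log-normal single-cell distribution is a
stand-in — the real marginal is not published — and the generator does
not emulate library-size variation, gene–gene correlation beyond the
shared latent, or UMI sampling noise; passing tests demonstrate
estimator correctness and calibration, not realism of scRNA-seq noise.

**Virtual tumor.**  A sphere of configurable radius centered in a gland
"breast" region inside a fat background, with vessels placed uniformly
at random among non-tumor voxels at the configured density and leakiness
drawn N(mean, sd) clamped to [0, 1].  A sphere is the simplest shape
with an analytic volume (the voxelization is required to match
(4/3)πr³ within 10%); irregular morphologies are a configuration
extension, not a default.  Deterministic fixed-geometry phantoms (vessel
shells defined in mm) are used where tests need resolution-independent
geometry, e.g. the grid-refinement check.

**Cohorts.**  Features are independent U(0, 1); outcome ~
Bernoulli(expit(c0 + c1·metab + c2·angio)) with defaults
(0, −2.5, +2.5): metabolic activity depresses and angiogenesis raises
pCR odds, matching the direction of the fitted biomarker.  Default size
292 with 54% TNBC, the composition of the published virtual-trial
cohort.

All generators take an integer seed and are bit-reproducible.

## Published tables as inputs

`tumorio.datasets` ships the printed validation-cohort score/call table
(n = 17) and the virtual-trial counts (158 TNBC, 134 HR+/HER2−; control
and predicted pCR counts forced by the printed rates and denominators:
106/158, 24/134, 61/158, 12/134).  These are inputs to the statistics
layer, used to confirm that the implemented formulas reproduce the
printed accuracy (88.2%), sub-tallies (10/12, 5/5) and all four exact
CIs to one decimal.

## Known limitations

- The nutrient model is a deliberate simplification (linear uptake, no
  flow, no PK/PD); features are comparable across tumors under the same
  configuration but are not calibrated to physical glucose units.
- Leakiness is consumed, never derived; angiogenesis features are only
  as meaningful as the supplied leakiness field.
- The linear probability model can emit scores outside [0, 1]; only the
  ranking and threshold matter for classification.
- Problem sizes in tests and the acceptance script (2,000 cells, ≤ 66³
  voxel phantoms, 10,000-replicate coverage grids) were chosen as the
  smallest sizes at which the statistical tolerances are meaningful.
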