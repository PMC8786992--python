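# Methods

This note documents the statistical model behind `radrepro`, the numerical
choices made where the method leaves room, and what the synthetic-data
generator does and does not emulate.

## Concordance

Lin's CCC between two setting columns uses moment estimators with divisor
*n* (the classical definition), consistently in variances, covariances and
the squared mean difference. The overall coefficient (OCCC) is

    OCCC = 2 Σ_{j<k} S_jk / [ (J−1) Σ_j S_j² + Σ_{j<k} (μ_j − μ_k)² ],

algebraically a weighted mean of pairwise CCCs with weights
`S_j² + S_k² + (μ_j − μ_k)²` — the form used as an independent oracle in the
tests. The n vs n−1 choice matters: mean-difference terms do not rescale
with the variance divisor, so switching conventions changes OCCC. We fix
divisor *n* and document it; exact numerical parity with other software is
not guaranteed.

Degenerate cases: if all columns are constant and equal, OCCC is defined as
1 (perfect agreement, logged); constant but unequal columns give a zero
numerator over a positive mean-difference denominator, hence OCCC = 0. No
confidence intervals are computed (point estimates are the decision input).

## The per-feature mixed model

Response: one feature's value per (patient, setting). Fixed effects:
intercept, setting (categorical against the reference, FBP by default),
scanner model, tube voltage (each dummy-coded against the lexicographically
first level) and tumour volume in cm³ (raw scale by default; a log option
exists). Random effect: a patient intercept. Features that *are* the
segmented volume (`original_shape_VoxelVolume` by default, extensible)
drop the volume covariate.

Estimation is REML on the profiled likelihood of the variance ratio
λ = σ_b²/σ_e². With a single random intercept the marginal covariance is
block compound-symmetric, so each candidate λ admits a closed-form GLS step
(Woodbury inverse per patient block); the REML criterion is minimised over
log λ ∈ [−14, 14] by bounded scalar optimisation (absolute tolerance
1e−10), with λ = 0 evaluated explicitly as the boundary candidate. When the
data contain no residual noise the optimum sits at the upper bound and the
reported residual variance resolves to ~σ_b²/λ_max rather than exactly
zero. Non-convergence falls back to λ = 0 (ordinary regression) with a
flag. The fit is cross-checked in the test suite against an independent
REML implementation (statsmodels `MixedLM`) on identical data.

Inference uses t statistics with the between-within degrees-of-freedom
convention: within-patient terms (setting contrasts) get
`df = n_obs − n_patients − n_within_terms`; between-patient terms
(intercept, scanner, voltage, volume) get
`df = n_patients − n_between_terms − 1`. Satterthwaite or Kenward–Roger
corrections are deliberately not attempted: at ~100 patients the
conventions agree to well beyond the decision threshold, and the
between-within rule is exactly reproducible. On a balanced complete design
each setting coefficient equals the mean over patients of (value at that
setting − value at the reference), which the tests assert to 1e−10.

All setting terms are fitted in one joint multivariable model together with
scanner, voltage and volume. FDR adjustment is applied per term family
across features (all setting contrasts jointly; scanner, voltage and volume
each jointly), matching the granularity at which the families are reported.
The adjustment scope for other batches (univariate tests, pairwise
sensitivity analysis) is "as submitted": each analysis batch is adjusted
jointly.

## Rank and contingency tests

Mann–Whitney uses the exact null distribution when the combined sample is
≤ 20 without ties, and signed-rank when the effective (nonzero) sample is
≤ 25 without ties; otherwise both use the tie-corrected normal
approximation with continuity correction. Zero differences in the
signed-rank test are dropped before ranking (classic Wilcoxon rather than
Pratt — the default of the mainstream implementations). Categorical
baseline variables use Pearson's χ² when every expected cell count is ≥ 5
and Fisher's exact test otherwise; for r×c tables where an exact
computation is unavailable a seeded Monte-Carlo p value over tables with
fixed margins is used and labelled as such.

## Classification and harmonization

The four groups are the literal 2×2 partition of OCCC (≥/< 0.85) against
the FDR-adjusted setting p (</≥ 0.05), with the boundary landing on the
"≥" branch on both axes. Per-contrast groups use the contrast's own p; the
overall group uses the minimum p across contrasts, so a feature is overall
non-significant (group 2 or 4) only if no contrast is significant — the
strict reading of "reproducible at every blending level".

Harmonization subtracts the fitted setting coefficient from every
observation at that setting (additive correction, implied by the additive
fixed-effect model); the reference column passes through bit-identically,
and coefficients are estimated in-sample from the same table being
corrected. On balanced data a refit of the corrected table returns setting
coefficients of zero to 1e−8 (asserted). A multiplicative or
location-scale (ComBat-style) correction is out of scope.

## Redundancy clustering

The clustering criterion is a *minimum intra-cluster* absolute Spearman
correlation of 0.75. The criterion names no algorithm; complete-linkage
agglomeration on the distance `1 − |ρ|` with the tree cut at `1 − 0.75` is
chosen because complete linkage bounds the maximum intra-cluster distance,
so the construction provably enforces the criterion. The invariant is
nevertheless re-audited on every produced partition. Features are processed
in lexicographic name order for deterministic tie-breaking; constant
features (undefined ρ) are excluded with a warning. Clustering defaults to
original-image features at the reference setting. Each cluster's
representative is the member with the highest median `|ρ|` to its cluster.

## Synthetic generator

The generator draws from the generative counterpart of the fitted model:

    value(i, j, f) = intercept_f + b_{i,f} + β_f(j)
                     + scanner/voltage/volume terms + u_{i,j,f} + ε_{i,j,f}

with patient intercepts `b ~ N(0, σ_b²)`, an i.i.d. patient-by-setting
interaction `u ~ N(0, σ_u²)` and residual noise `ε ~ N(0, σ_e²)`. Setting
effects are linear in the blending percent by default, with a random sign
per feature, reflecting the monotone smoothing response most texture
features show to increasing IR strength; arbitrary per-setting effects are
supported.

The cohort structure mirrors the study design it emulates: 103 patients,
two scanner models and two tube voltages split ~50/50, six settings (FBP,
IR20–IR80), complete observation, and log-normal tumour volumes truncated
to the 5–200 cm³ inclusion window (log-mean 3.55, log-SD 0.75, giving a
median near 35 cm³). Scanner/voltage effects and volume slopes default to
zero — the emulated study found no significant scanner or voltage
dependence — but are available for power studies.

The four planted regimes (in units of σ_b = 1): group 1 has max |β| = 0.3
and σ_e = 0.1; group 2 has β = 0 and σ_e = 0.1; group 3 has max |β| = 3
and σ_e = 0.3; group 4 has β = 0, σ_e = 0.1 and σ_u = 1.5. These constants
were calibrated once so the full pipeline recovers the planted regimes at
study scale and then frozen. The group-4 mechanism is an i.i.d.
patient-by-setting deviation rather than a common per-patient slope: a
shared random slope would induce within-patient correlation across setting
contrasts that the random-intercept analysis model does not absorb,
inflating the per-contrast type-I error and contradicting both the planted
definition (no systematic trend, p ≥ 0.05) and the verbal description of
the regime (sign and size of the variation random across patients).

What the generator does **not** emulate: inter-feature correlation beyond
optionally duplicated/transformed features (so redundancy-cluster counts on
default synthetic tables are trivially one cluster per feature),
heavy-tailed or skewed feature distributions, volume-dependent
heteroscedasticity, segmentation variability, and any image-level process.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the assumed model, not robustness to real-data
violations of it.

## Problem sizes and determinism

The default test and acceptance workloads use the study-scale cohort (103
patients, 6 settings) with tens of features per regime, 20–50 simulation
replicates for recovery rates, 200–500 replicates for estimator bias,
coverage and harmonization-benefit checks, and 1000 random matrices for the
concordance oracle — sizes chosen so the whole suite completes in a couple
of minutes while keeping Monte-Carlo error well inside the asserted
margins. All randomness flows through explicit seeds; the pipeline writes
CSVs sorted by feature and a manifest without timestamps, so identical
configurations produce byte-identical bundles.

## Known limitations

* Exact numerical parity with other mixed-model software is expected for
  coefficients but only approximate (optimizer tolerance) for variance
  components; p values depend on the df convention documented above.
* The harmonization is in-sample; cross-fitted or external-reference
  correction is future work.
* Complete-case handling of missing cells is a package convention; the
  emulated design is complete by construction.
* The univariate scanner/voltage analysis assumes exactly two scanners and
  two voltages; larger factorial designs are out of scope.
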