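# radrepro

Reproducibility analysis of radiomic features across CT reconstruction
settings.

When a retrospective CT database mixes images reconstructed with different
iterative-reconstruction (IR) blending levels — from pure filtered
backprojection (FBP, 0% blending) up to strong IR — the values of radiomic
features extracted from the same lesion can shift systematically with the
reconstruction setting, confounding any downstream radiomic model. This
package implements an integrative pipeline for quantifying and handling
that dependence, for medical physicists and radiomics researchers who need
to decide, feature by feature, what is reproducible, what is correctable,
and what must be discarded.

## The method

For each feature, observed on every patient under every reconstruction
setting:

1. **Concordance.** The overall concordance correlation coefficient (OCCC)
   over the *J* settings,

   `OCCC = 2 Σ_{j<k} S_jk / [ (J−1) Σ_j S_j² + Σ_{j<k} (μ_j − μ_k)² ]`,

   the multi-rater generalisation of Lin's CCC (a weighted mean of all
   pairwise CCCs). OCCC ≥ 0.85 flags within-patient setting variation as
   small relative to the between-patient spread.

2. **Mixed model.** A multivariable linear mixed model per feature,

   `y_ij = β₀ + β_setting(j) + β_s·scanner_i + β_v·voltage_i + β_c·volume_i + b_i + ε_ij`,

   with a random patient intercept `b_i`, the setting as a categorical
   factor against a reference (FBP), fitted by REML via a profiled
   likelihood on the variance ratio. Each non-reference setting gets a
   coefficient and a p value; p values are Benjamini–Hochberg FDR-adjusted
   per term family across features.

3. **Four-group classification.** Crossing OCCC (≥ / < 0.85) with the
   FDR-adjusted setting p (< / ≥ 0.05) separates features into: group 1
   (small systematic shift — correctable), group 2 (small random variation
   — reproducible as-is), group 3 (large systematic trend — recoverable
   after correction), group 4 (large random variation — reject).

4. **Harmonization.** For groups 1 and 3, subtracting the fitted setting
   coefficient from every non-reference observation removes the common
   trend; reference-setting values are untouched.

5. **Redundancy.** Complete-linkage clustering on `1 − |Spearman ρ|`, cut
   so that every pair of features sharing a cluster has `|ρ| ≥ 0.75`.

Supporting analyses: Wilcoxon–Mann–Whitney comparisons of feature values
between scanners and tube voltages, a baseline clinical-characteristics
table (χ² / Fisher exact / Mann–Whitney), and a pairwise signed-rank
sensitivity analysis across all setting pairs.

A synthetic generator (`radrepro.simulate`) produces study-shaped feature
tables — 103 patients, two scanners × two voltages, six settings, features
planted in each of the four regimes — with full ground truth, so every
stage is testable by recovery.

## Worked example

```python
import radrepro as rr

table, truth = rr.simulate(rr.get_preset("paper_shaped", seed=3))
res = rr.ReproducibilityStudy(table).fit()
print(res.summary())
```

```
Radiomic feature reproducibility study
==============================================
patients:       103
settings:       FBP, IR20, IR40, IR50, IR60, IR80 (reference FBP)
features:       106
OCCC < 0.85:    15/106 features
overall groups: G1: 66.0%  G2: 19.8%  G3: 11.3%  G4: 2.8%
```

15 of 106 features fall below the 0.85 concordance threshold (the planted
large-trend and large-interaction features), and the overall-group
percentages recover the planted mixture: most features show a small but
systematic trend (group 1), a minority a large correctable trend (group 3),
and very few are irrecoverably noisy (group 4). Downstream:

```python
harm = res.harmonize()          # subtract fitted setting coefficients
clusters = res.cluster()        # redundancy clusters, min |rho| >= 0.75
fit = res.mixed_fits[0]         # per-feature statsmodels-style results
print(fit.summary())
```

The command-line interface mirrors the library
(`radrepro simulate|analyze|harmonize|cluster|report`); `report` writes the
full CSV bundle plus a JSON manifest, bit-identical across reruns with the
same seed.

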