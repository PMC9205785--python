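# synomics

Analysis toolkit for biopsy-driven treatment-response studies in
rheumatoid arthritis: synovial tissue is biopsied before and after
therapy, profiled by bulk RNA-seq and semiquantitative
immunohistochemistry, and related to the clinical response to two
biologics (rituximab, anti-CD20; tocilizumab, anti-IL6R) with a
per-protocol crossover for nonresponders.

The package implements the full analysis chain on that design:

* **Clinical/histology model** — CDAI (0–76) and the CDAI 50% response
  endpoint, crossover outcome labels (responder / pro-rituximab /
  pro-tocilizumab / refractory), the immune score (0–25), and rule-based
  synovial **pathotype** classification (lymphomyeloid / diffuse-myeloid /
  pauci-immune-fibroid) from CD20/CD138/CD68SL scores, with two published
  rule variants.
* **Expression preparation** — median-of-ratios size factors, LOQ / CV /
  low-expression filters, log normalization, correlation pruning and
  top-variance feature selection.
* **Deconvolution** — marker-mean cell-population scores, rich/poor
  stratification at the cohort median, combined B-cell × myeloid strata,
  and bin-matched gene-set module scores.
* **Longitudinal NB mixed models** — the core. For each gene g with
  counts Y_ijg of patient i at visit j:

      Y_ijg ~ NB(mu_ijg, alpha_g)
      log mu_ijg = o_ij + beta_g0 + beta_g1 time_ij + beta_g2 medication_i
                   + beta_g3 time_ij * medication_i + b_gi,
      b_gi ~ N(0, sigma_gb^2)

  with o_ij a log library-size offset, time and arm coded {0,1}, and a
  per-patient random intercept.  Dispersion alpha_g is estimated by
  Cox–Reid adjusted profile likelihood (paired design, trend-shrunken),
  the marginal likelihood is maximized via the Laplace approximation,
  inference is by marginality-respecting (type-2) Wald chi-square tests
  with Storey q-values, and genes are classified as shared-time /
  drug-dominant from the interaction term and per-arm fold changes.
* **Association statistics** — Fisher's exact test with conditional-MLE
  odds ratio and exact CI (the R `fisher.test` conventions),
  Mann–Whitney / Wilcoxon rank tests, BH adjustment, and longitudinal
  CDAI arm comparisons with a mixed-model interaction test.
* **Response prediction** — 10×10 nested cross-validation with in-fold
  univariate/RFE feature selection and an elastic-net logistic reference
  learner; AUC by the rank statistic.
* **Synthetic cohorts** — generators for counts (with stored ground
  truth), histology scores (latent-factor copula) and CDAI trajectories,
  emulating the trial's scale (133 patients, 44 with paired biopsies,
  two arms).

## Worked example

```python
from synomics.simulate import SimulationConfig, generate_counts
from synomics.glmm import fit_all
from synomics.stats import fisher_exact

# a small paired two-arm cohort with 2% true time x medication effects
cfg = SimulationConfig(n_patients=40, n_paired=40, n_genes=500,
                       frac_interaction_genes=0.02,
                       fixed_effect_magnitude=1.0, seed=11)
data, truth = generate_counts(cfg)
res = fit_all(data, seed=0)
print(res.label.value_counts().to_dict())
print("interaction hits:",
      sorted(res.index[res.q_time_x_group < 0.05]))
print("true interaction genes:", sorted(truth.interaction_genes))

# the diffuse-myeloid stratum's 2x2 response table
print(fisher_exact([[13, 3], [7, 13]]))
```

Output:

```
{'unclassified': 363, 'drug2_dominant': 10}
interaction hits: ['G00018', 'G00057', 'G00082', 'G00218', 'G00238', 'G00300', 'G00335', 'G00402', 'G00471', 'G00492']
true interaction genes: ['G00057', 'G00082', 'G00218', 'G00238', 'G00300', 'G00335', 'G00402', 'G00448', 'G00471', 'G00492']
FisherResult(p_value=0.007908557939993835, odds_ratio=7.533743562985951, ci_low=1.4126986274513653, ci_high=55.665025856075125)
```

Nine of the ten interaction calls are planted genes (one planted gene,
G00448, was removed by the low-expression filter; one call, G00018, is a
false positive), and the 2×2 test reproduces the printed trial statistics
to their precision: p = 0.008, odds ratio 7.53, 95% CI 1.4–55.7.

A command-line interface mirrors the library
(`synomics simulate | pathotype | deconvolve | fit-longitudinal | stats |
predict | run`); every subcommand takes `--dry-run`.

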