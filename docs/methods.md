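# Methods

This note documents the models and procedures `synomics` implements, the
parameters that matter, the numerical choices, and what the synthetic
cohorts do and do not emulate.

## Clinical and histological model

CDAI is the arithmetic sum of tender joints (0–28), swollen joints
(0–28) and two 0–10 global assessments; the response endpoint is a ≥50%
improvement from baseline at 16 weeks, with the exact-50% case counted
as response.  Nonresponders switch to the alternative biologic;
crossover outcomes are labelled responder-first, pro-rituximab /
pro-tocilizumab (response to the second drug after failure of the
first), or refractory (sequential failure of both).

Pathotype classification ships with two rulesets because the published
figure-legend and methods-text criteria differ.  The `figure` ruleset
(default, the one attached to the stratified response analyses) is:
lymphomyeloid if CD20 ≥ 2 or CD138 ≥ 2; else diffuse-myeloid if
CD68SL ≥ 2; else pauci-immune-fibroid.  Precedence lymphomyeloid >
diffuse-myeloid > pauci-immune resolves overlaps, "and/or" is read as
OR, and the ruleset is total over complete score triples (property-tested
over the full 5×5×5 grid).  The `methods` ruleset adds the CD20-aggregate
grade and CD3 clauses and is deliberately not total: score combinations
matching no clause return `ungraded` rather than being forced into a
class.  The immune score is Krenn (0–9) plus CD20, CD3, CD138 and CD68
sublining (0–4 each); the sublining macrophage score is the CD68
component used throughout, since it is the one the response analyses
stratify on.

## Negative binomial mixed models for paired biopsies

For each gene, counts Y_ijg of patient i at visit j follow
NB(mu_ijg, alpha_g) with variance mu + alpha mu², and

    log mu_ijg = o_ij + b0 + b1·time_ij + b2·group_i + b3·time_ij·group_i + b_gi,
    b_gi ~ N(0, sigma²_gb),

where time is 0/1 for the 0/16-week visits, `group` is the medication
arm (or responder status in the per-drug variant — the design matrix is
identical), and o_ij = log(L_ij / median L) so the intercept is
interpretable at the median library.  Only patients with both visits are
fitted.  Zero counts are replaced by a pseudo-count of 0.125 before the
mixed fit; the likelihood uses the gamma-function form and accepts the
non-integer response.

**Dispersion.**  alpha_g is estimated before the mixed fit and held
fixed, by maximizing the Cox–Reid adjusted profile likelihood of a
fixed-effects NB regression, bounded to [1e-8, 10].  For the paired
design the profile design matrix contains patient indicators plus the
within-patient terms: without them, between-patient variability is
absorbed into alpha (simulations show bias ≈ +0.24 at sigma_b = 0.5) and
the downstream interaction test becomes severely conservative.  The
gene-wise estimates are then shrunk toward a parametric mean-dispersion
trend alpha(mu) = a0 + a1/mu (robust IRLS fit) by a log-normal prior
whose variance is the excess of the robust spread of log residuals over
the approximate sampling variance trigamma((m−p)/2), floored at 0.25;
genes more than 2 robust SDs above the trend keep their gene-wise value.
This moderation mirrors the standard two-stage count-model estimator and
halves the error of individual dispersions; `dispersion_moderation=False`
restores raw gene-wise values.

**Fitting.**  The marginal likelihood integrates the random intercept
per patient; the Laplace approximation replaces each integral with a
second-order expansion at the penalized mode.  Modes are found by damped
1-D Newton iterations (vectorized over patients, gradient tolerance
1e-8, warm-started across nearby parameter values — the warm start
changes nothing numerically, only speed).  The outer search is
bound-constrained L-BFGS over (beta, log sigma) with sigma in
[1e-4, 10]; an explicit sigma = 0 boundary candidate (a plain
fixed-effects NB fit by Fisher scoring) is compared against the interior
optimum and wins ties, which makes the sigma² → 0 limit exactly the
fixed-effects model (verified against an independent GLM implementation
to 1e-3).  On non-convergence the search restarts from two seed-derived
perturbed starts.  The coefficient covariance V is the inverse
observed-information block for beta at the optimum (finite-difference
Hessian of the Laplace objective, conditional on the variance parameter,
as linear-mixed-model practice does).  Validation: on small instances at
moderate expression the Laplace marginal log-likelihood agrees with
25-node adaptive Gauss–Hermite quadrature to < 1e-2; the gap vanishes in
the Poisson limit (alpha·mu → 0) and grows with sigma² and alpha, since
the NB working information saturates at 1/alpha — agreement at high
expression is therefore a property of mild dispersion, not of count
magnitude.

**Inference.**  Per-term type-2 Wald chi-square tests respect
marginality via the difference construction: the statistic for a term is
the joint Wald test of the term plus its containing interaction minus
the joint test of the interaction alone; for the interaction itself this
is (beta3/SE)².  The chi-square tail is averaged over the posterior
uncertainty of the plug-in dispersion (9-node Gauss–Hermite over a
log-normal perturbation of the Wald variance, with elasticity
d log V / d log alpha ≈ mean of alpha·mu/(1+alpha·mu)).  Treating the
estimated dispersion as exactly known leaves the far tail of the null
distribution 1.5–2× heavier than nominal at these sample sizes, which
inflates the false discovery proportion of the interaction screen;
with the propagation the null tail is calibrated (simulated type-I error
4–6% at nominal 5%, and ≈1e-3 at nominal 1e-3) while the statistic and
its chi-square reference are unchanged.  `dispersion_logsd=0` restores
the plain tail.

**Multiplicity.**  Storey q-values per term.  The null-proportion
estimate pi0 defaults to the single-lambda tail estimator
#{p > 0.5}/(m/2): at panel sizes of a few thousand tests with sparse
alternatives it is nearly unbiased with SD ≈ 0.02, whereas smoothing the
lambda grid and extrapolating to lambda = 0.95 rests on few p-values and
underestimates pi0 (overstating significance) in a sizeable fraction of
simulated datasets.  The grid smoother remains available
(`method="smoother"`), and pi0 = 1 reduces the q-values exactly to
Benjamini–Hochberg.  Interaction genes are classified at FDR < 0.05:
significant interaction → dominant drug by larger |log2 FC over time|
(arm 0: b1·log2 e; arm 1: (b1+b3)·log2 e); otherwise significant time
effect → shared change; otherwise unclassified.

**Predictions.**  Fitted means use fixed effects only (b = 0);
prediction variances are the diagonal of X V Xᵀ and 95% intervals are
exp(eta ± 1.96·SE), optionally scaled by a reference offset.

## Exact and rank statistics

The 2×2 machinery follows the conventions of the R implementation whose
outputs the trial reports: two-sided p by the point-probability rule,
odds ratio as the conditional MLE under the noncentral hypergeometric
model, and an exact CI from inverting one-sided conditional tests at
(1−conf)/2 per side.  Against full enumeration the p-values agree to
1e-10 and the OR to 1e-4 on random tables with margins ≤ 40.  Degenerate
margins give p = 1 with the OR flagged undefined.  Mann–Whitney and
Wilcoxon tests use midranks, tie-corrected normal approximations with
continuity correction, and exact enumeration for small tie-free samples
(≤12 combined / ≤15 nonzero).  The longitudinal CDAI comparison runs
per-visit Mann–Whitney tests (BH-adjusted across visits) and tests the
arm × time interaction with a linear mixed model (patient random
intercept, baseline CDAI covariate) — a documented surrogate for
repeated-measures ANCOVA, whose exact construction is not specified in
the source material.

## Response prediction

Features are transformed expression (top-variance protein-coding genes,
correlation-pruned at |r| > 0.9) plus clinical/histology columns.
Nested cross-validation: stratified outer folds estimate generalization;
inner folds tune the number of selected features ({25, 30, 50, 100} by
default) and the elastic-net penalty, maximizing inner accuracy at the
0.5 threshold; ties prefer fewer features.  Feature selection (two-sample
t filter, or RFE halving by coefficient magnitude) and standardization
are computed on training patients only.  The final model is refit on all
patients at the mean tuned hyperparameters, and coefficients double as
importance.  The design's correctness property is the leakage guard:
on label-permuted data the mean outer AUC stays in [0.45, 0.55], and a
perfectly separating feature yields AUC 1.  AUC is the rank statistic
U/(n1·n0) with midranks, which makes it identical to the Mann–Whitney U
normalization.

## Synthetic cohorts

Defaults mirror the trial scale: 133 patients (44 with paired biopsies),
two arms, 2,000 genes, 2% of genes with a nonzero time × medication
interaction.  Counts are gamma–Poisson draws from the model above.
Distributions the source does not state are conventions chosen once:
baseline log-means N(3, 1.5²); per-gene dispersions
lognormal(meanlog −1.5, sdlog 0.5) (median ≈ 0.22); library sizes
lognormal around 10⁷ (sdlog 0.35); random-intercept SD 0.5.  Interaction
effects are N(0, sd) by default or ±magnitude with random sign
(`fixed_effect_magnitude`), the variant used for power/FDR harnesses.
Histology scores threshold a shared per-patient latent inflammation
factor (correlation rho) into equal-probability ordinal bins; CDAI
trajectories are linear in months with arm/stratum slopes, patient
intercepts and noise, clamped to 0–76 and back-filled into components
that sum exactly to the total.  One root seed feeds fixed per-generator
streams, so enlarging the gene panel never changes the clinical draws,
and regeneration is bit-identical.

What the generators do **not** emulate: library-size–expression
coupling, batch effects, gene–gene correlation, dropout structure,
informative missingness of the optional second biopsy, or ordinal rater
noise in histology.  Passing recovery and calibration tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data features.

## Validation problem sizes

The self-validation harnesses (`synomics.benchmarks`, run by
`scripts/acceptance.py`) use: 50 random ≤5-patient instances for the
quadrature comparison; 500 genes × 40 paired patients for recovery and
CI coverage; 2,000 null genes for type-I error; three pooled replicates
of the 2,000-gene default cohort for the interaction screen's observed
FDR and sensitivity (pooling stabilizes a rate whose numerator is a
handful of false positives per replicate); 200 random tables for the
enumeration check; and 20 label permutations of a 100-patient ×
500-feature matrix for the leakage guard.  These sizes give stable
estimates at desk scale; the rates themselves, not the sizes, are the
claims.

## Known limitations

Laplace (not quadrature) likelihoods; a single random intercept (no
crossed or nested effects); only the two trial model variants, not a
general formula interface; the Wald tail propagation treats the
dispersion uncertainty as log-normal and per-gene independent; the
repeated-measures ANCOVA surrogate above; elastic-net logistic as the
one built-in learner (others plug in via the fit/score/importance
contract).  The published real-data gene counts and model AUCs require
the deposited cohort and are out of scope for the synthetic harnesses.
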