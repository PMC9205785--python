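"""Self-validation harnesses.

Each function regenerates its inputs from a seed, runs the relevant part of
the package, and measures a calibration or recovery quantity: the printed
2x2 trial table, enumeration cross-checks of the exact test, Laplace
vs quadrature agreement, the sigma^2 = 0 reduction, coefficient recovery
and CI coverage, null calibration (type-I error), FDR/sensitivity of the
interaction screen, the nested-CV leakage guard, and the pathotype rule
grid.  `scripts/acceptance.py` writes these numbers out; the acceptance
test suite asserts their expected bands.
"""

from __future__ import annotations

import itertools
from typing import Dict

import numpy as np
import pandas as pd
from scipy.special import gammaln
from numpy.polynomial.hermite_e import hermegauss

from synomics.clinical import BiopsyScores, Pathotype, classify_pathotype
from synomics.glmm import (
    dispersion_design,
    estimate_dispersion,
    fit_all,
    fit_gene,
    laplace_loglik,
    pseudo_count_adjust,
)
from synomics.predict import FeatureSpace, nested_cv
from synomics.qvalue import qvalues
from synomics.simulate import SimulationConfig, generate_counts
from synomics.stats import fisher_exact

# the published diffuse-myeloid stratum: tocilizumab 13/16 responders versus
# rituximab 7/20
DIFFUSE_MYELOID_TABLE = ((13, 3), (7, 13))


def fisher_printed_analysis() -> Dict[str, float]:
    res = fisher_exact(np.array(DIFFUSE_MYELOID_TABLE))
    return {"p": res.p_value, "odds_ratio": res.odds_ratio,
            "ci_low": res.ci_low, "ci_high": res.ci_high}


# -- enumeration oracle for the exact test ---------------------------------

def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _nchg(psi, m1, m2, n):
    lo, hi = max(0, n - m2), min(n, m1)
    ks = np.arange(lo, hi + 1)
    logw = _log_binom(m1, ks) + _log_binom(m2, n - ks) + ks * np.log(psi)
    logw -= logw.max()
    w = np.exp(logw)
    return ks, w / w.sum()


def fisher_vs_enumeration(seed: int, n_tables: int = 200,
                          max_margin: int = 40) -> Dict[str, float]:
    """Compare p and conditional-MLE OR against full noncentral
    hypergeometric enumeration on random tables with margins <= max_margin."""
    from scipy.optimize import brentq
    rng = np.random.default_rng(seed)
    max_p_gap = 0.0
    max_or_relgap = 0.0
    done = 0
    while done < n_tables:
        a, b, c, d = (int(v) for v in rng.integers(0, max_margin // 2, size=4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        res = fisher_exact([[a, b], [c, d]])
        m1, m2, n = a + b, c + d, a + c
        ks, p0 = _nchg(1.0, m1, m2, n)
        obs = p0[ks == a][0]
        p_enum = p0[p0 <= obs * (1 + 1e-9)].sum()
        max_p_gap = max(max_p_gap, abs(res.p_value - p_enum))
        if ks.min() < a < ks.max():
            or_enum = np.exp(brentq(
                lambda lg: (lambda kk, pp: (kk * pp).sum())(*_nchg(np.exp(lg), m1, m2, n)) - a,
                -50, 50))
            max_or_relgap = max(max_or_relgap,
                                abs(res.odds_ratio - or_enum) / or_enum)
        done += 1
    return {"max_p_gap": max_p_gap, "max_or_relgap": max_or_relgap,
            "n": n_tables}


# -- Laplace vs adaptive quadrature ----------------------------------------

def _quadrature_loglik(beta, sigma2, y, X, offset, idx, alpha, n_nodes=25):
    """Adaptive Gauss-Hermite marginal log-likelihood with per-patient
    modes located by grid search plus Newton polish (no reuse of the
    Laplace mode finder)."""
    nodes, weights = hermegauss(n_nodes)
    eta_fixed = X @ beta + offset
    r = 1.0 / alpha

    def nb_ll(yv, mu):
        return (gammaln(yv + r) - gammaln(r) - gammaln(yv + 1)
                + r * np.log(r / (r + mu)) + yv * np.log(mu / (r + mu)))

    total = 0.0
    for i in np.unique(idx):
        rows = idx == i
        yi, ei = y[rows], eta_fixed[rows]

        def g(bv):
            return nb_ll(yi, np.exp(ei + bv)).sum() - bv**2 / (2 * sigma2)

        grid = np.linspace(-6, 6, 1501)
        bhat = grid[np.argmax([g(bv) for bv in grid])]
        h = 1e-4
        d2 = (g(bhat + h) - 2 * g(bhat) + g(bhat - h)) / h**2
        d1 = (g(bhat + h) - g(bhat - h)) / (2 * h)
        if d2 < 0:
            bhat -= d1 / d2
            d2 = (g(bhat + h) - 2 * g(bhat) + g(bhat - h)) / h**2
        s = 1.0 / np.sqrt(-d2)
        pts = bhat + s * nodes
        logt = np.array([g(bv) for bv in pts]) + nodes**2 / 2 + np.log(weights) + np.log(s)
        m = logt.max()
        total += m + np.log(np.exp(logt - m).sum()) - 0.5 * np.log(2 * np.pi * sigma2)
    return total


def laplace_vs_quadrature(seed: int, n_instances: int = 50) -> Dict[str, float]:
    """Max |Laplace - 25-node adaptive quadrature| marginal log-likelihood
    over random <= 5-patient instances at moderate expression and mild
    dispersion (where the expansion's own error is well under the gap that
    would indicate an implementation defect)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_pat = int(rng.integers(3, 6))
        rows, idx, off = [], [], []
        for i in range(n_pat):
            for t in (0, 1):
                rows.append([1.0, t, i % 2, t * (i % 2)])
                idx.append(i)
                off.append(rng.normal(0, 0.2))
        X, idx, off = np.array(rows), np.array(idx), np.array(off)
        beta = rng.normal([4.0, 0, 0, 0], [0.5, 0.3, 0.3, 0.3])
        sigma2 = rng.uniform(0.02, 0.15)
        alpha = rng.uniform(0.02, 0.15)
        b = rng.normal(0, np.sqrt(sigma2), n_pat)
        mu = np.exp(X @ beta + off + b[idx])
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu)).astype(float)
        y[y == 0] = 0.125
        gap = abs(laplace_loglik(beta, sigma2, y, X, off, idx, alpha)
                  - _quadrature_loglik(beta, sigma2, y, X, off, idx, alpha))
        worst = max(worst, gap)
    return {"max_loglik_gap": worst, "n": n_instances}


def sigma_zero_reduction(seed: int, n_genes: int = 5) -> Dict[str, float]:
    """Max |beta difference| between the sigma^2 = 0 boundary fit and an
    independent fixed-effects NB regression (statsmodels GLM)."""
    import statsmodels.api as sm
    from synomics.glmm import _irls_nb
    cfg = SimulationConfig(n_patients=20, n_paired=20, n_genes=n_genes,
                           sigma_b=0.0, frac_interaction_genes=0.0, seed=seed)
    data, truth = generate_counts(cfg)
    X, idx = data.design()
    off = data.offsets
    worst = 0.0
    for i in range(n_genes):
        y = pseudo_count_adjust(data.counts.iloc[i])
        alpha = float(truth.alpha.iloc[i])
        beta, _ = _irls_nb(np.asarray(y, float), X, off, alpha)
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=off).fit()
        worst = max(worst, float(np.max(np.abs(beta - glm.params))))
    return {"max_coef_gap": worst, "n": n_genes}


def recovery_and_coverage(seed: int, n_genes: int = 500,
                          n_paired: int = 40) -> Dict[str, float]:
    """Coefficient recovery on generator output with known truth: mean bias
    of the time coefficient and 95% Wald CI coverage across genes."""
    cfg = SimulationConfig(n_patients=n_paired, n_paired=n_paired,
                           n_genes=n_genes, sigma_b=0.5,
                           frac_interaction_genes=0.02, seed=seed)
    data, truth = generate_counts(cfg)
    X, idx = data.design()
    off = data.offsets
    D = dispersion_design(X, idx)
    bias, cover = [], []
    for i in range(n_genes):
        raw = data.counts.iloc[i].to_numpy(float)
        alpha = estimate_dispersion(raw, D, off)
        fit = fit_gene(pseudo_count_adjust(raw), X, off, idx, alpha, seed=0)
        if not fit.converged:
            continue
        true_b1 = truth.beta.beta1.iloc[i]
        bias.append(fit.beta[1] - true_b1)
        se = np.sqrt(fit.vcov[1, 1])
        cover.append(abs(fit.beta[1] - true_b1) <= 1.959964 * se)
    return {"beta1_mean_bias": float(np.mean(bias)),
            "ci_coverage_pct": 100.0 * float(np.mean(cover)),
            "n": len(bias)}


def type1_error(seed: int, n_genes: int = 2000) -> Dict[str, float]:
    """Fraction of null genes with interaction p < 0.05 through the full
    per-gene pipeline."""
    cfg = SimulationConfig(n_genes=n_genes, sigma_b=0.5,
                           frac_interaction_genes=0.0, seed=seed)
    data, _ = generate_counts(cfg)
    res = fit_all(data, seed=0)
    p = res.p_time_x_group.dropna().to_numpy()
    return {"type1_pct": 100.0 * float((p < 0.05).mean()), "n": len(p)}


def fdr_and_sensitivity(seed: int, n_reps: int = 3) -> Dict[str, float]:
    """Observed FDR and sensitivity of the interaction screen (q < 0.05) at
    the trial-scale defaults with 2% true interaction genes of |beta3| = 1,
    pooled over independent replicates for a stable rate estimate."""
    tp = fp = n_true = 0
    for r in range(n_reps):
        cfg = SimulationConfig(sigma_b=0.5, frac_interaction_genes=0.02,
                               fixed_effect_magnitude=1.0,
                               seed=seed + 7919 * r)
        data, truth = generate_counts(cfg)
        res = fit_all(data, seed=0)
        aff = res.index.isin(truth.interaction_genes)
        sig = (res.q_time_x_group < 0.05).to_numpy()
        tp += int((sig & aff).sum())
        fp += int((sig & ~aff).sum())
        n_true += int(aff.sum())
    return {"observed_fdr": fp / max(tp + fp, 1),
            "sensitivity_pct": 100.0 * tp / max(n_true, 1),
            "n": n_reps}


def leakage_guard(seed: int, n_perms: int = 20, n_patients: int = 100,
                  n_features: int = 500) -> Dict[str, float]:
    """Mean outer AUC of the nested CV on label-permuted data (must hover
    at 0.5 -- in-fold selection is what makes this hold) and the AUC with a
    perfectly separating feature (must be 1)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n_patients, n_features)),
                     index=[f"pt{i}" for i in range(n_patients)],
                     columns=[f"f{j}" for j in range(n_features)])
    y0 = pd.Series(np.repeat([0, 1], n_patients // 2), index=X.index)
    aucs = []
    for k in range(n_perms):
        y = pd.Series(rng.permutation(y0.to_numpy()), index=X.index)
        res = nested_cv(FeatureSpace(X, y), k_outer=10, k_inner=10,
                        n_features_grid=(25, 50, 100),
                        penalty_grid=(0.1,), seed=seed + k)
        aucs.append(res.mean_outer_auc)
    Xs = X.iloc[:, :20].copy()
    Xs["sep"] = y0 * 5.0 + rng.normal(scale=0.05, size=n_patients)
    perfect = nested_cv(FeatureSpace(Xs, y0), k_outer=10, k_inner=5,
                        n_features_grid=(5,), penalty_grid=(0.01,),
                        seed=seed).mean_outer_auc
    return {"null_mean_auc": float(np.mean(aucs)),
            "perfect_feature_auc": float(perfect), "n": n_perms}


def qvalue_bh_agreement(seed: int, n: int = 2000) -> Dict[str, float]:
    """Max |q - BH| with pi0 fixed at 1 (must be 0 to numerical precision)."""
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    gap = np.max(np.abs(qvalues(p, pi0=1.0)
                        - multipletests(p, method="fdr_bh")[1]))
    return {"max_abs_gap": float(gap), "n": n}


def pathotype_grid() -> Dict[str, float]:
    """Exhaustive 5x5x5 grid under the figure ruleset: every cell must get
    exactly one informative label; the three published worked examples must
    classify as printed."""
    labeled = 0
    for cd20, cd138, cd68sl in itertools.product(range(5), repeat=3):
        lab = classify_pathotype(
            BiopsyScores(cd20=cd20, cd138=cd138, cd68sl=cd68sl), "figure")
        if lab is not Pathotype.UNGRADED:
            labeled += 1
    examples = [
        ((3, 2, 3), Pathotype.LYMPHOMYELOID),
        ((1, 1, 2), Pathotype.DIFFUSE_MYELOID),
        ((0, 0, 0), Pathotype.PAUCI_IMMUNE_FIBROID),
    ]
    correct = sum(
        classify_pathotype(BiopsyScores(cd20=a, cd138=b, cd68sl=c),
                           "figure") is expect
        for (a, b, c), expect in examples)
    return {"grid_cells_labeled": labeled, "examples_correct": correct,
            "n": 125}
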