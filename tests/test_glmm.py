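"""NB mixed-model machinery: dispersion estimation, Laplace fit against an
adaptive Gauss-Hermite quadrature oracle, the sigma = 0 reduction against an
independent fixed-effects fit, Wald tests, predictions and the whole-matrix
driver."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import gammaln
from scipy.stats import norm

from synomics.glmm import (
    GeneFit,
    LongitudinalCountData,
    TERMS,
    classify_interaction_genes,
    dispersion_design,
    estimate_dispersion,
    fit_all,
    fit_gene,
    laplace_loglik,
    pseudo_count_adjust,
    predict_with_ci,
    wald_type2,
)
from synomics.simulate import SimulationConfig, generate_counts


# ---------------------------------------------------------------------------
# oracle: adaptive Gauss-Hermite marginal likelihood (independent of the
# Laplace code path)
# ---------------------------------------------------------------------------

def nb_logpmf(y, mu, alpha):
    r = 1.0 / alpha
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


def agq_loglik(beta, sigma2, y, X, offset, idx, alpha, n_nodes=25):
    """Adaptive Gauss-Hermite marginal log-likelihood, centered and scaled
    at each patient's penalized mode found by dense grid + polish."""
    nodes, weights = hermegauss(n_nodes)  # probabilists' weights, integrate vs e^{-x^2/2}
    total = 0.0
    eta_fixed = X @ beta + offset
    for i in np.unique(idx):
        rows = idx == i
        yi, ei = y[rows], eta_fixed[rows]

        def g(b):
            mu = np.exp(ei + b)
            return nb_logpmf(yi, mu, alpha).sum() - b**2 / (2 * sigma2)

        grid = np.linspace(-6, 6, 2001)
        vals = np.array([g(b) for b in grid])
        bhat = grid[np.argmax(vals)]
        # quadratic polish
        h = 1e-4
        d1 = (g(bhat + h) - g(bhat - h)) / (2 * h)
        d2 = (g(bhat + h) - 2 * g(bhat) + g(bhat - h)) / h**2
        if d2 < 0:
            bhat -= d1 / d2
            d2 = (g(bhat + h) - 2 * g(bhat) + g(bhat - h)) / h**2
        s = 1.0 / np.sqrt(-d2)
        # integral of exp(g(b)) db via adaptive GH with kernel e^{-x^2/2}
        pts = bhat + s * nodes
        gv = np.array([g(b) for b in pts])
        log_terms = gv + nodes**2 / 2.0 + np.log(weights) + np.log(s)
        m = log_terms.max()
        log_int = m + np.log(np.exp(log_terms - m).sum())
        total += log_int - 0.5 * np.log(2 * np.pi * sigma2)
    return total


def _random_instance(rng, n_pat=4):
    X_rows, idx, off = [], [], []
    for i in range(n_pat):
        for t in (0, 1):
            X_rows.append([1.0, t, i % 2, t * (i % 2)])
            idx.append(i)
            off.append(rng.normal(0, 0.2))
    X = np.array(X_rows)
    idx = np.array(idx)
    off = np.array(off)
    # moderately expressed, mildly dispersed instances: the Laplace error
    # per patient grows with sigma^2 and alpha (the NB working information
    # saturates at 1/alpha, so the gap does NOT vanish at high expression);
    # within these ranges the method's own approximation error stays well
    # under the comparison tolerance and the check isolates implementation
    # defects (see test_gap_vanishes_in_poisson_limit for the scaling)
    beta = rng.normal([4.0, 0, 0, 0], [0.5, 0.3, 0.3, 0.3])
    sigma2 = rng.uniform(0.02, 0.15)
    alpha = rng.uniform(0.02, 0.15)
    b = rng.normal(0, np.sqrt(sigma2), n_pat)
    mu = np.exp(X @ beta + off + b[idx])
    y = rng.poisson(rng.gamma(1 / alpha, alpha * mu)).astype(float)
    y[y == 0] = 0.125
    return y, X, off, idx, beta, sigma2, alpha


class TestLaplaceAgainstQuadrature:
    def test_loglik_matches_agq_on_random_instances(self):
        rng = np.random.default_rng(31)
        diffs = []
        for _ in range(50):
            n_pat = int(rng.integers(3, 6))
            y, X, off, idx, beta, sigma2, alpha = _random_instance(rng, n_pat)
            ll_lap = laplace_loglik(beta, sigma2, y, X, off, idx, alpha)
            ll_agq = agq_loglik(beta, sigma2, y, X, off, idx, alpha)
            diffs.append(abs(ll_lap - ll_agq))
        assert max(diffs) < 1e-2

    def test_gap_vanishes_in_poisson_limit(self):
        """As alpha -> 0 at high expression the conditional likelihood in b
        becomes sharply Gaussian and the Laplace error must vanish -- the
        signature of a correctly centered and scaled expansion."""
        rng = np.random.default_rng(8)
        y, X, off, idx, beta, sigma2, _ = _random_instance(rng, 4)
        beta = beta.copy()
        beta[0] = 7.0   # the limit needs alpha * mu << 1, so mu must be large
        gaps = []
        for alpha in (0.5, 0.05, 0.002):
            mu = np.exp(X @ beta + off)
            yy = rng.poisson(rng.gamma(1 / alpha, alpha * mu)).astype(float)
            yy[yy == 0] = 0.125
            gaps.append(abs(
                laplace_loglik(beta, sigma2, yy, X, off, idx, alpha)
                - agq_loglik(beta, sigma2, yy, X, off, idx, alpha)))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 5e-4

    def test_maximizer_agrees_with_agq_maximizer(self):
        from scipy.optimize import minimize
        rng = np.random.default_rng(77)
        for _ in range(3):
            y, X, off, idx, beta, sigma2, alpha = _random_instance(rng, 5)
            fit = fit_gene(y, X, off, idx, alpha, seed=0)
            if fit.sigma2 == 0:
                continue

            def agq_nll(theta):
                return -agq_loglik(theta[:4], float(np.exp(2 * theta[4])),
                                   y, X, off, idx, alpha)

            start = np.concatenate([fit.beta, [0.5 * np.log(fit.sigma2)]])
            res = minimize(agq_nll, start, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8,
                                    "maxiter": 4000})
            assert np.max(np.abs(res.x[:4] - fit.beta)) < 1e-2


class TestDispersion:
    @staticmethod
    def _design(n):
        X = np.column_stack([np.ones(n), np.arange(n) % 2,
                             (np.arange(n) // 2) % 2,
                             (np.arange(n) % 2) * ((np.arange(n) // 2) % 2)])
        return X, np.zeros(n)

    def test_poisson_limit(self, rng):
        X, off = self._design(200)
        y = rng.poisson(30, size=200).astype(float)
        assert estimate_dispersion(y, X, off) < 0.05

    def test_recovers_known_dispersion(self, rng):
        X, off = self._design(200)
        alpha = 0.5
        estimates = []
        for _ in range(30):
            mu = 25.0
            y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=200))
            estimates.append(estimate_dispersion(y.astype(float), X, off))
        assert 0.4 < np.median(estimates) < 0.6

    def test_constant_counts_hit_lower_bound(self):
        X, off = self._design(40)
        y = np.full(40, 12.0)
        assert estimate_dispersion(y, X, off) < 1e-4


class TestPseudoCount:
    def test_rules(self):
        assert pseudo_count_adjust([0])[0] == 0.125
        assert pseudo_count_adjust([5])[0] == 5
        assert np.allclose(pseudo_count_adjust([0, 1, 0]), [0.125, 1, 0.125])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pseudo_count_adjust([-1])


class TestFitGene:
    def test_no_random_effect_recovers_beta0(self):
        cfg = SimulationConfig(
            n_patients=200, n_paired=200, n_genes=1, sigma_b=0.0,
            frac_interaction_genes=0.0, base_mean_log_params=(1.0, 0.0),
            dispersion_lognormal_params=(np.log(0.1), 0.0),
            libsize_lognormal_params=(16.0, 0.0), seed=17)
        data, truth = generate_counts(cfg)
        X, idx = data.design()
        y = pseudo_count_adjust(data.counts.iloc[0])
        fit = fit_gene(y, X, data.offsets, idx, 0.1, seed=0)
        assert abs(fit.beta[0] - 1.0) < 0.05
        assert fit.sigma2 < 0.02

    def test_sigma_zero_matches_independent_fixed_fit(self, small_cohort):
        data, truth = small_cohort
        X, idx = data.design()
        off = data.offsets
        for i in range(5):
            y = pseudo_count_adjust(data.counts.iloc[i])
            alpha = float(truth.alpha.iloc[i])
            ll0 = laplace_loglik(np.zeros(4), 0.0, y, X, off, idx, alpha)
            assert np.isfinite(ll0)
            # statsmodels GLM as the independent oracle at sigma^2 = 0
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=off).fit()
            from synomics.glmm import _irls_nb
            beta, _ = _irls_nb(np.asarray(y, float), X, off, alpha)
            assert np.max(np.abs(beta - glm.params)) < 1e-3
            ll_impl = laplace_loglik(beta, 0.0, np.asarray(y, float), X, off,
                                     idx, alpha)
            assert abs(ll_impl - glm.llf) < 1e-3

    def test_requires_enough_pairs(self):
        X = np.array([[1.0, 0, 0, 0], [1.0, 1, 0, 0]] * 2)
        idx = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError):
            fit_gene(np.array([3.0, 4, 5, 6]), X, np.zeros(4), idx, 0.1)


class TestWald:
    @staticmethod
    def _fit(beta, V):
        return GeneFit(np.asarray(beta, float), np.asarray(V, float), 0.1,
                       0.2, -10.0, True)

    def test_zero_interaction_coefficient(self):
        fit = self._fit([1, 0.5, 0.2, 0.0], np.eye(4) * 0.04)
        res = wald_type2(fit)
        assert res["time:group"][0] == 0.0
        assert res["time:group"][2] == 1.0

    def test_one_df_equals_z_squared(self):
        V = np.diag([0.1, 0.04, 0.09, 0.25])
        fit = self._fit([1, 0.8, -0.3, 0.5], V)
        res = wald_type2(fit)
        assert res["time:group"][0] == pytest.approx(0.5**2 / 0.25)
        # with a diagonal V the difference construction also reduces to z^2
        assert res["time"][0] == pytest.approx(0.8**2 / 0.04)

    def test_reduces_to_z2_without_interaction_correlation(self, rng):
        A = rng.normal(size=(4, 4))
        V = A @ A.T + np.eye(4)
        V[3, :] = V[:, 3] = 0.0
        V[3, 3] = 0.2
        fit = self._fit([1, 0.5, 0.3, 0.1], V)
        res = wald_type2(fit)
        assert res["time"][0] == pytest.approx(0.5**2 / V[1, 1])

    def test_singular_block_flags_missing(self):
        V = np.zeros((4, 4))
        fit = self._fit([1, 0.5, 0.3, 0.1], V)
        res = wald_type2(fit)
        assert np.isnan(res["time:group"][2])


class TestPredictWithCi:
    def test_zero_variance(self):
        fit = GeneFit(np.array([1.0, 0.5, 0.0, 0.0]), np.zeros((4, 4)),
                      0.0, 0.1, -5.0, True)
        out = predict_with_ci(fit, [[1, 1, 0, 0]])
        assert out["fitted"][0] == pytest.approx(np.exp(1.5))
        assert out["ci_low"][0] == out["ci_high"][0] == out["fitted"][0]

    def test_single_coefficient_interval(self):
        se = 0.3
        fit = GeneFit(np.array([2.0]), np.array([[se**2]]), 0.0, 0.1, -5.0,
                      True, coef_names=("intercept",))
        out = predict_with_ci(fit, [[1.0]])
        assert out["ci_low"][0] == pytest.approx(np.exp(2.0 - norm.ppf(0.975) * se))
        assert out["ci_high"][0] == pytest.approx(np.exp(2.0 + norm.ppf(0.975) * se))

    def test_monte_carlo_quantiles(self, rng):
        beta = np.array([1.0, 0.4, -0.2, 0.1])
        A = rng.normal(size=(4, 4)) * 0.1
        V = A @ A.T + 0.01 * np.eye(4)
        fit = GeneFit(beta, V, 0.0, 0.1, -5.0, True)
        Xn = np.array([[1.0, 1.0, 1.0, 1.0]])
        out = predict_with_ci(fit, Xn)
        draws = rng.multivariate_normal(beta, V, size=10000)
        etas = draws @ Xn[0]
        lo, hi = np.exp(np.quantile(etas, [0.025, 0.975]))
        assert out["ci_low"][0] == pytest.approx(lo, rel=0.02)
        assert out["ci_high"][0] == pytest.approx(hi, rel=0.02)

    def test_bad_design_row(self):
        fit = GeneFit(np.zeros(4), np.eye(4), 0.0, 0.1, -5.0, True)
        with pytest.raises(ValueError):
            predict_with_ci(fit, [[1.0, 0.0]])


class TestFitAll:
    def test_gene_order_permutation(self, small_cohort):
        data, _ = small_cohort
        res = fit_all(data, apply_filter=False, dispersion_moderation=False,
                      seed=0)
        perm = data.counts.sample(frac=1, random_state=5)
        data2 = LongitudinalCountData(perm, data.metadata)
        res2 = fit_all(data2, apply_filter=False, dispersion_moderation=False,
                       seed=0)
        # identical per-gene coefficients and test statistics, permuted rows
        joined = res.drop(columns=["label"]).join(
            res2.drop(columns=["label"]), rsuffix="_p")
        for col in ("log2fc_arm0", "chisq_time_x_group", "alpha"):
            assert np.allclose(joined[col], joined[col + "_p"], equal_nan=True)

    def test_empty_after_filter_warns(self, small_cohort):
        data, _ = small_cohort
        ones = LongitudinalCountData(data.counts * 0 + 1, data.metadata)
        with pytest.warns(UserWarning):
            res = fit_all(ones, seed=0)
        assert res.empty

    def test_refuses_too_few_pairs(self):
        cfg = SimulationConfig(n_patients=10, n_paired=2, n_genes=5, seed=0)
        data, _ = generate_counts(cfg)
        with pytest.raises(ValueError):
            fit_all(data)

    def test_interaction_effects_recovered(self, small_cohort):
        data, truth = small_cohort
        res = fit_all(data, apply_filter=False, seed=0)
        aff = res.index.isin(truth.interaction_genes)
        # strong planted effects (|beta3| = 1.5, 20 pairs) should dominate
        # the interaction ranking
        top = res["p_time_x_group"].nsmallest(3).index
        assert sum(g in truth.interaction_genes for g in top) >= 2


class TestClassification:
    def test_rules(self):
        res = pd.DataFrame({
            "q_time": [0.01, 0.5, 0.5, 0.2],
            "q_time_x_group": [0.2, 0.01, 0.5, 0.01],
            "log2fc_arm0": [1.0, 2.0, 0.1, 0.5],
            "log2fc_arm1": [1.0, 0.5, 0.1, 2.0],
        }, index=list("abcd"))
        labels = classify_interaction_genes(res, fdr=0.05)
        assert labels["a"] == "time_shared"
        assert labels["b"] == "drug1_dominant"
        assert labels["c"] == "unclassified"
        assert labels["d"] == "drug2_dominant"
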