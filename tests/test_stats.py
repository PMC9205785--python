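"""Exact 2x2 machinery against a brute-force noncentral-hypergeometric
oracle, rank tests against enumeration, BH adjustment, and the CDAI course
comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import gammaln

from synomics.stats import (
    ContingencyTable2x2,
    bh_fdr,
    cdai_group_course_test,
    fisher_exact,
    mann_whitney,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent oracle: noncentral hypergeometric enumeration
# ---------------------------------------------------------------------------

def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def nchg_pmf(psi, m1, m2, n):
    """Support and probabilities of cell `a` under the noncentral
    hypergeometric distribution with margins (m1, m2) row totals and n
    first-column total."""
    lo, hi = max(0, n - m2), min(n, m1)
    ks = np.arange(lo, hi + 1)
    logw = _log_binom(m1, ks) + _log_binom(m2, n - ks) + ks * np.log(psi)
    logw -= logw.max()
    w = np.exp(logw)
    return ks, w / w.sum()


def oracle_fisher(a, b, c, d, conf=0.95):
    m1, m2, n = a + b, c + d, a + c
    ks, p0 = nchg_pmf(1.0, m1, m2, n)
    obs = p0[ks == a][0]
    p_two = p0[p0 <= obs * (1 + 1e-9)].sum()

    def mean_a(psi):
        ks_, p_ = nchg_pmf(psi, m1, m2, n)
        return (ks_ * p_).sum()

    lo, hi = ks.min(), ks.max()
    if a == hi:
        or_mle = np.inf
    elif a == lo:
        or_mle = 0.0
    else:
        or_mle = brentq(lambda lg: mean_a(np.exp(lg)) - a, -50, 50)
        or_mle = np.exp(or_mle)

    def p_upper(psi):   # P(X >= a | psi)
        ks_, p_ = nchg_pmf(psi, m1, m2, n)
        return p_[ks_ >= a].sum()

    def p_lower(psi):   # P(X <= a | psi)
        ks_, p_ = nchg_pmf(psi, m1, m2, n)
        return p_[ks_ <= a].sum()

    half = (1 - conf) / 2
    ci_lo = 0.0 if a == lo else np.exp(
        brentq(lambda lg: p_upper(np.exp(lg)) - half, -50, 50))
    ci_hi = np.inf if a == hi else np.exp(
        brentq(lambda lg: p_lower(np.exp(lg)) - half, -50, 50))
    return p_two, or_mle, ci_lo, ci_hi


class TestFisher:
    def test_symmetric_table(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_small_table_enumeration(self):
        res = fisher_exact([[2, 1], [1, 2]])
        p, orr, lo, hi = oracle_fisher(2, 1, 1, 2)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.odds_ratio == pytest.approx(orr, rel=1e-5)

    def test_random_tables_against_oracle(self, rng):
        for _ in range(40):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = fisher_exact([[a, b], [c, d]])
            p, orr, lo, hi = oracle_fisher(int(a), int(b), int(c), int(d))
            assert res.p_value == pytest.approx(p, abs=1e-10)
            if np.isfinite(orr) and orr > 0:
                assert res.odds_ratio == pytest.approx(orr, rel=1e-4)
            if 0 < lo and np.isfinite(hi):
                assert res.ci_low == pytest.approx(lo, rel=1e-3)
                assert res.ci_high == pytest.approx(hi, rel=1e-3)

    def test_ci_inversion_property(self):
        # at each CI endpoint the one-sided conditional p equals 0.025
        a, b, c, d = 13, 3, 7, 13
        res = fisher_exact([[a, b], [c, d]])
        m1, m2, n = a + b, c + d, a + c
        ks, p_at_lo = nchg_pmf(res.ci_low, m1, m2, n)
        assert p_at_lo[ks >= a].sum() == pytest.approx(0.025, abs=1e-4)
        ks, p_at_hi = nchg_pmf(res.ci_high, m1, m2, n)
        assert p_at_hi[ks <= a].sum() == pytest.approx(0.025, abs=1e-4)

    def test_degenerate_margin(self):
        res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0 and res.odds_ratio is None

    def test_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 1, 2)
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # n_x * n_y / 2
        assert res.p_value == pytest.approx(1.0, abs=0.02)

    def test_fully_separated_exact(self):
        res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        # 2 / C(8,4)
        assert res.p_value == pytest.approx(2 / 70, abs=1e-12)

    def test_u_identity(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 15))
            y = rng.normal(size=rng.integers(2, 15))
            ux = mann_whitney(x, y).statistic
            uy = mann_whitney(y, x).statistic
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_close_to_normal_approx(self, rng):
        # n = 12 per group forces the asymptotic path; compare with scipy exact
        from scipy.stats import mannwhitneyu
        x = rng.normal(size=12)
        y = rng.normal(0.3, size=12)
        approx = mann_whitney(x, y).p_value
        exact = mannwhitneyu(x, y, method="exact").pvalue
        assert abs(approx - exact) < 0.01

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_positive_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 2**6, abs=1e-12)

    def test_antisymmetric_at_null_mean(self):
        d = [1.5, -1.5, 2.5, -2.5]
        res = wilcoxon_signed_rank(d)
        # W equals n(n+1)/4 = 5 at perfect antisymmetry
        assert res.statistic == pytest.approx(5.0)
        assert res.p_value > 0.9

    def test_pair_order_invariance(self, rng):
        d = rng.normal(size=20)
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(d[::-1])
        assert a == b

    def test_all_zero(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_value == 1.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_never_below_input(self, rng):
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p).all()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCdaiCourse:
    @staticmethod
    def _course(rng, effect=0.0, n=30):
        rows = []
        for i in range(n):
            arm = "A" if i % 2 == 0 else "B"
            base = rng.uniform(25, 45)
            for month in range(5):
                slope = -1.0 + (effect if arm == "B" else 0.0)
                val = np.clip(base + slope * month + rng.normal(0, 2), 0, 76)
                rows.append({"patient_id": f"p{i}", "visit_month": month,
                             "medication": arm, "cdai": val})
        return pd.DataFrame(rows)

    def test_identical_arms_nonsignificant(self, rng):
        res = cdai_group_course_test(self._course(rng, effect=0.0))
        assert res.interaction_p > 0.05
        assert (res.per_visit_p_adjusted > 0.05).all()

    def test_arm_swap_symmetry(self, rng):
        df = self._course(rng, effect=-3.0)
        res = cdai_group_course_test(df)
        swapped = df.assign(medication=df["medication"].map({"A": "B", "B": "A"}))
        res2 = cdai_group_course_test(swapped)
        assert np.allclose(res.per_visit_p, res2.per_visit_p)
        assert res.interaction_p == pytest.approx(res2.interaction_p, rel=1e-6)

    def test_strong_interaction_detected(self, rng):
        res = cdai_group_course_test(self._course(rng, effect=-5.0, n=60))
        assert res.interaction_p < 0.05

    def test_interaction_power_on_generated_courses(self):
        """A large arm-specific slope in the generator is detected by the
        interaction test in nearly every replicate (n = 60 per arm)."""
        from synomics.simulate import SimulationConfig, generate_cdai_course
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_patients=120, n_paired=10, seed=seed)
            df = generate_cdai_course(cfg, stratum_effects={"all": -4.0})
            hits += cdai_group_course_test(df).interaction_p < 0.05
        assert hits >= 8
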