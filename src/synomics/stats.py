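"""Exact and rank-based statistics for stratified response analysis.

The 2x2 machinery follows the R ``fisher.test`` conventions the trial's
printed results use: two-sided p by the point-probability rule, odds ratio
as the conditional maximum-likelihood estimate under the noncentral
hypergeometric model, and an exact CI obtained by inverting one-sided
conditional tests at (1 - conf)/2 per side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a,b / c,d; rows = medication arm, columns = responder /
    nonresponder."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name}={v} must be a nonnegative integer")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


class FisherResult(NamedTuple):
    p_value: float
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]


def fisher_exact(table, conf_level: float = 0.95) -> FisherResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio and
    exact confidence interval.

    Degenerate margins (an empty row or column) carry no information about
    association: p = 1 and the odds ratio is flagged undefined (None).
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("expected a 2x2 table of nonnegative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return FisherResult(1.0, None, None, None)
    p = float(sps.fisher_exact(arr, alternative="two-sided").pvalue)
    orr = _conditional_odds_ratio(arr, kind="conditional")
    ci = orr.confidence_interval(confidence_level=conf_level)
    return FisherResult(p, float(orr.statistic), float(ci.low), float(ci.high))


class RankTestResult(NamedTuple):
    statistic: float
    p_value: float


def mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration when the combined sample has <= 12 observations and no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def wilcoxon_signed_rank(paired_diffs) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; exact distribution when <= 15 nonzero
    differences without ties in |d|, else normal approximation with tie and
    continuity corrections.  All-zero differences give p = 1 with a warning.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero")
        return RankTestResult(0.0, 1.0)
    no_ties = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (nz.size <= 15 and no_ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", zero_method="wilcox",
                       correction=(method == "approx"), method=method)
    return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class CourseTestResult(NamedTuple):
    per_visit_p: pd.Series           # raw two-sided Mann-Whitney per visit
    per_visit_p_adjusted: pd.Series  # BH across visits
    interaction_p: float


def cdai_group_course_test(
    course_table: pd.DataFrame,
    arm_col: str = "medication",
    value_col: str = "cdai",
    visit_col: str = "visit_month",
    patient_col: str = "patient_id",
) -> CourseTestResult:
    """Compare CDAI trajectories between the two arms within a stratum.

    Per visit: two-sided Mann-Whitney across arms, BH-adjusted over visits.
    The arm x time interaction is tested by a linear mixed model of CDAI on
    arm, time and their interaction with a patient random intercept and the
    patient's baseline CDAI as covariate (a mixed-model stand-in for
    repeated-measures ANCOVA), Wald test on the interaction coefficient.
    Missing visits are handled available-case.
    """
    df = course_table[[patient_col, visit_col, arm_col, value_col]].dropna().copy()
    arms = sorted(df[arm_col].unique())
    if len(arms) != 2:
        raise ValueError(f"expected exactly two arms, got {arms}")
    per_visit = {}
    for visit, sub in df.groupby(visit_col):
        g0 = sub.loc[sub[arm_col] == arms[0], value_col]
        g1 = sub.loc[sub[arm_col] == arms[1], value_col]
        if len(g0) < 2 or len(g1) < 2:
            warnings.warn(f"visit {visit}: fewer than 2 patients per arm, skipped")
            continue
        per_visit[visit] = mann_whitney(g0, g1).p_value
    pv = pd.Series(per_visit).sort_index()
    adj = pd.Series(bh_fdr(pv.to_numpy()), index=pv.index) if len(pv) else pv.copy()

    baseline = (df[df[visit_col] == df[visit_col].min()]
                .set_index(patient_col)[value_col].rename("baseline"))
    post = df[df[visit_col] > df[visit_col].min()].join(baseline, on=patient_col)
    post = post.dropna(subset=["baseline"])
    post["arm01"] = (post[arm_col] == arms[1]).astype(float)
    model = smf.mixedlm(
        f"{value_col} ~ arm01 * {visit_col} + baseline",
        data=post, groups=post[patient_col],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    interaction_p = float(fit.pvalues[f"arm01:{visit_col}"])
    return CourseTestResult(pv, adj, interaction_p)
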