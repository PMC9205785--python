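"""Nested cross-validated treatment-response prediction.

Outer folds estimate generalization; inner folds tune the number of
selected features and the learner's hyperparameters.  Feature selection
(univariate t-statistic filter or coefficient-based recursive elimination)
and standardization are computed on training patients only -- the leakage
guard that makes the null AUC land at 0.5 -- and the final model is refit
on all patients at the mean of the outer-fold tuned hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

DEFAULT_N_FEATURES = (25, 30, 50, 100)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def univariate_filter(train_X: pd.DataFrame, train_y, n_features: int) -> List[str]:
    """Rank features by two-sample t statistic magnitude between classes on
    the training patients and keep the top n (ties by feature id)."""
    y = np.asarray(train_y).astype(int)
    X = train_X.to_numpy(dtype=float)
    if n_features >= X.shape[1]:
        if n_features > X.shape[1]:
            warnings.warn("requested more features than available; keeping all")
        return list(train_X.columns)
    g1, g0 = X[y == 1], X[y == 0]
    n1, n0 = len(g1), len(g0)
    diff = g1.mean(axis=0) - g0.mean(axis=0)
    var1 = g1.var(axis=0, ddof=1) if n1 > 1 else np.zeros(X.shape[1])
    var0 = g0.var(axis=0, ddof=1) if n0 > 1 else np.zeros(X.shape[1])
    se = np.sqrt(var1 / max(n1, 1) + var0 / max(n0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff != 0, np.inf, 0.0))
    order = sorted(range(X.shape[1]),
                   key=lambda j: (-abs(t[j]), str(train_X.columns[j])))
    return [train_X.columns[j] for j in order[:n_features]]


def rfe_filter(train_X: pd.DataFrame, train_y, n_features: int,
               penalty_weight: float = 1.0, mixing: float = 0.5) -> List[str]:
    """Recursive feature elimination using the reference learner's
    coefficient magnitudes, halving the feature count per step."""
    cols = list(train_X.columns)
    if n_features >= len(cols):
        return cols
    while len(cols) > n_features:
        target = max(n_features, len(cols) // 2)
        model = reference_learner_fit(_standardize(train_X[cols])[0], train_y,
                                      penalty_weight, mixing)
        imp = np.abs(model.coef)
        order = sorted(range(len(cols)), key=lambda j: (-imp[j], str(cols[j])))
        cols = sorted((cols[j] for j in order[:target]), key=str)
    return cols


@dataclass
class LinearScorer:
    """Fitted penalized logistic model: coefficients double as feature
    importance."""

    coef: np.ndarray
    intercept: float
    features: List[str]

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.features].to_numpy(dtype=float) @ self.coef + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


def reference_learner_fit(train_X: pd.DataFrame, train_y,
                          penalty_weight: float = 1.0,
                          mixing: float = 0.5) -> LinearScorer:
    """Elastic-net-penalized binomial regression.

    Minimizes the penalized binomial negative log-likelihood with penalty
    lambda * [(1-mixing)/2 * ||b||^2 + mixing * ||b||_1]; the intercept is
    unpenalized.  ``mixing`` = 0 is ridge, 1 is lasso.
    """
    if not (0.0 <= mixing <= 1.0):
        raise ValueError("mixing must lie in [0, 1]")
    if penalty_weight < 0:
        raise ValueError("penalty weight must be nonnegative")
    y = np.asarray(train_y).astype(int)
    n = len(y)
    if penalty_weight == 0:
        penalty_weight = 1e-8  # ridge fallback keeps collinear designs solvable
        warnings.warn("zero penalty; using a vanishing ridge for stability")
    # sklearn's C is 1/(n * lambda) for the mean-log-likelihood objective
    C = 1.0 / (n * penalty_weight)
    if mixing == 0.0:
        model = LogisticRegression(penalty="l2", C=C, solver="lbfgs",
                                   max_iter=5000, tol=1e-7)
    else:
        model = LogisticRegression(penalty="elasticnet", l1_ratio=mixing, C=C,
                                   solver="saga", max_iter=5000, tol=1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(train_X.to_numpy(dtype=float), y)
    return LinearScorer(model.coef_.ravel().copy(), float(model.intercept_[0]),
                        list(train_X.columns))


def roc_auc(scores, labels) -> float:
    """AUC via the rank statistic with midrank ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _standardize(X: pd.DataFrame, mean=None, sd=None):
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (X - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass
class FeatureSpace:
    """Patients x features matrix plus binary outcome labels.  Missing
    values must already be imputed; standardization happens inside folds."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self):
        self.y = pd.Series(self.y).loc[self.X.index].astype(int)
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if set(self.y.unique()) - {0, 1}:
            raise ValueError("labels must be binary 0/1")


@dataclass
class NestedCVResult:
    outer_auc: List[float]
    inner_omitted_auc: List[float]
    tuned_params: List[Dict]
    selected_features: List[List[str]]
    pooled_scores: pd.DataFrame
    final_model: Optional[LinearScorer]
    feature_importance: Optional[pd.Series]

    @property
    def mean_outer_auc(self) -> float:
        return float(np.mean(self.outer_auc))

    @property
    def mean_inner_auc(self) -> float:
        return float(np.mean(self.inner_omitted_auc))


def _fit_candidate(Xtr: pd.DataFrame, ytr, n_feat, lam, mixing, filter_mode):
    Xs, mean, sd = _standardize(Xtr)
    if filter_mode == "rfe":
        feats = rfe_filter(Xtr, ytr, n_feat, lam, mixing)
    else:
        feats = univariate_filter(Xtr, ytr, n_feat)
    model = reference_learner_fit(Xs[feats], ytr, lam, mixing)
    return model, feats, mean, sd


def nested_cv(
    features: FeatureSpace,
    k_outer: int = 10,
    k_inner: int = 10,
    n_features_grid: Sequence[int] = DEFAULT_N_FEATURES,
    penalty_grid: Sequence[float] = (0.01, 0.1),
    mixing_grid: Sequence[float] = (0.5,),
    filter_mode: str = "univariate",
    seed: int = 0,
) -> NestedCVResult:
    """10x10 nested cross-validation with in-fold feature selection.

    Inner CV picks (n_features, penalty, mixing) maximizing inner accuracy
    (proportion correct at probability 0.5); ties prefer fewer features and
    stronger penalty (parsimony).  The winning configuration is refit on the
    outer-training set and scored on the held-out outer fold; AUC is also
    recorded on the samples each inner split omitted.  The final model is a
    refit on all patients at the mean tuned hyperparameters.  Deterministic
    given the seed.
    """
    if filter_mode not in ("univariate", "rfe"):
        raise ValueError(f"unknown filter mode {filter_mode!r}")
    X, y = features.X, features.y
    class_n = y.value_counts().min()
    if class_n < k_outer:
        k_outer = max(2, int(class_n))
        warnings.warn(f"reduced outer folds to {k_outer} (smallest class)")
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)

    outer_auc, inner_auc, tuned, selected = [], [], [], []
    pooled = []
    grid = [
        (nf, lam, mx)
        for nf in sorted(set(min(nf, X.shape[1]) for nf in n_features_grid))
        for lam in penalty_grid for mx in mixing_grid
    ]
    for fold_id, (tr, te) in enumerate(outer.split(X, y)):
        Xtr, ytr = X.iloc[tr], y.iloc[tr]
        Xte, yte = X.iloc[te], y.iloc[te]
        k_in = min(k_inner, int(ytr.value_counts().min()))
        k_in = max(2, k_in)
        inner = StratifiedKFold(n_splits=k_in, shuffle=True,
                                random_state=seed + 1000 + fold_id)
        inner_splits = list(inner.split(Xtr, ytr))

        best = None  # (accuracy, -n_feat preference handled by ordering)
        for nf, lam, mx in grid:
            correct = total = 0
            omitted_scores, omitted_labels = [], []
            for itr, ite in inner_splits:
                Xi, yi = Xtr.iloc[itr], ytr.iloc[itr]
                try:
                    model, feats, mean, sd = _fit_candidate(Xi, yi, nf, lam, mx,
                                                            filter_mode)
                except Exception:
                    continue
                Xo = _standardize(Xtr.iloc[ite], mean, sd)[0]
                proba = model.predict_proba(Xo)
                correct += int(((proba >= 0.5).astype(int)
                                == ytr.iloc[ite].to_numpy()).sum())
                total += len(ite)
                omitted_scores.append(proba)
                omitted_labels.append(ytr.iloc[ite].to_numpy())
            if total == 0:
                continue
            acc = correct / total
            key = (acc, -nf, lam)  # parsimony on exact ties
            if best is None or key > best[0]:
                best = (key, (nf, lam, mx), omitted_scores, omitted_labels)
        if best is None:
            warnings.warn(f"outer fold {fold_id}: no candidate converged; skipped")
            continue
        _, (nf, lam, mx), om_s, om_l = best
        try:
            inner_auc.append(roc_auc(np.concatenate(om_s), np.concatenate(om_l)))
        except ValueError:
            pass
        model, feats, mean, sd = _fit_candidate(Xtr, ytr, nf, lam, mx, filter_mode)
        proba = model.predict_proba(_standardize(Xte, mean, sd)[0])
        try:
            outer_auc.append(roc_auc(proba, yte))
        except ValueError:
            warnings.warn(f"outer fold {fold_id}: single-class test fold")
            continue
        tuned.append({"n_features": nf, "penalty_weight": lam, "mixing": mx})
        selected.append(list(feats))
        pooled.append(pd.DataFrame({"patient": Xte.index, "score": proba,
                                    "label": yte.to_numpy(),
                                    "outer_fold": fold_id}))

    final_model = importance = None
    if tuned:
        nf = int(round(np.mean([t["n_features"] for t in tuned])))
        lam = float(np.mean([t["penalty_weight"] for t in tuned]))
        mx = float(np.mean([t["mixing"] for t in tuned]))
        final_model, feats, _, _ = _fit_candidate(X, y, nf, lam, mx, filter_mode)
        importance = pd.Series(np.abs(final_model.coef), index=feats,
                               name="importance").sort_values(ascending=False)
    pooled_df = (pd.concat(pooled, ignore_index=True) if pooled
                 else pd.DataFrame(columns=["patient", "score", "label",
                                            "outer_fold"]))
    return NestedCVResult(outer_auc, inner_auc, tuned, selected, pooled_df,
                          final_model, importance)
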