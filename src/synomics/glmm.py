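"""Per-gene negative binomial mixed-effects models for paired longitudinal
RNA-seq.

For each gene g the model is

    Y_ijg ~ NB(mu_ijg, alpha_g)          (variance mu + alpha mu^2)
    log mu_ijg = o_ij + beta_g0 + beta_g1 time_ij + beta_g2 group_i
                 + beta_g3 time_ij group_i + b_gi
    b_gi ~ N(0, sigma_gb^2)

with time coded {0,1} (weeks 0/16), group the medication arm (or responder
status in the per-drug variant), and o_ij the log library-size offset scaled
to the median library.  The marginal likelihood is maximized by the Laplace
approximation: per-patient random-intercept modes are found by damped 1-D
Newton iterations and the outer bound-constrained quasi-Newton search runs
over (beta, log sigma), with an explicit check of the sigma = 0 boundary
against a plain fixed-effects NB fit.

Dispersion is estimated gene-wise beforehand by maximizing the Cox-Reid
adjusted profile likelihood of a fixed-effects-only NB regression and held
fixed during the mixed fit.  Zero counts are replaced by a pseudo-count of
0.125 before fitting; the NB log-likelihood accepts the resulting
non-integer responses through its gamma-function form.  Inference per term
uses marginality-respecting (type-2) Wald chi-square tests and Storey
q-values across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2

from synomics.prep import filter_low_expressed
from synomics.qvalue import qvalues

PSEUDO_COUNT = 0.125
ALPHA_BOUNDS = (1e-8, 10.0)
_ETA_CLIP = 30.0
TERMS = ("time", "group", "time:group")
_LOG2E = 1.0 / np.log(2.0)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalCountData:
    """Raw counts with subject/timepoint/arm annotations and offsets.

    counts: genes x samples DataFrame.
    metadata: one row per sample with columns patient_id, time (0/1),
        group (0/1) and library_size.  Offsets are derived as
        log(library_size / median library_size).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        required = {"patient_id", "time", "group", "library_size"}
        missing = required - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.metadata.index):
            raise ValueError("metadata rows must match count columns exactly")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        lib = self.metadata["library_size"].to_numpy(dtype=float)
        if (lib <= 0).any() or not np.isfinite(lib).all():
            raise ValueError("library sizes must be positive and finite")

    @property
    def offsets(self) -> np.ndarray:
        lib = self.metadata["library_size"].to_numpy(dtype=float)
        return np.log(lib / np.median(lib))

    def paired_subset(self) -> "LongitudinalCountData":
        """Restrict to patients with both visits (the only ones that enter
        the mixed fit)."""
        visits = self.metadata.groupby("patient_id")["time"].nunique()
        keep_patients = set(visits.index[visits >= 2])
        mask = self.metadata["patient_id"].isin(keep_patients)
        return LongitudinalCountData(
            self.counts.loc[:, mask.to_numpy()], self.metadata.loc[mask]
        )

    def design(self) -> Tuple[np.ndarray, np.ndarray]:
        """(X, patient_index): model matrix [1, time, group, time*group] and
        the 0-based patient index per sample."""
        t = self.metadata["time"].to_numpy(dtype=float)
        g = self.metadata["group"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(t), t, g, t * g])
        codes, _ = pd.factorize(self.metadata["patient_id"], sort=True)
        return X, codes.astype(np.intp)


@dataclass
class GeneFit:
    """One gene's fitted mixed model."""

    beta: np.ndarray
    vcov: np.ndarray
    sigma2: float
    alpha: float
    loglik: float
    converged: bool
    coef_names: Tuple[str, ...] = ("intercept", "time", "group", "time:group")
    wald: Dict[str, Tuple[float, int, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# NB likelihood pieces (continuous-response gamma form)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


def pseudo_count_adjust(gene_counts) -> np.ndarray:
    """Replace zero counts by 0.125; other values untouched."""
    y = np.asarray(gene_counts, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    out = y.copy()
    out[out == 0] = PSEUDO_COUNT
    return out


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 40, tol: float = 1e-9,
             beta0: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed-effects NB regression via Fisher scoring.

    Returns (beta, W) with W the working weights mu/(1+alpha*mu) at the
    optimum.  Convergence is judged on the clipped linear predictor so that
    quasi-separated indicator columns (coefficients drifting to the clip
    boundary) terminate cleanly.  Used for starting values, the Cox-Reid
    profile and the sigma = 0 boundary fit.
    """
    if beta0 is None:
        eta = np.clip(np.log(np.maximum(y, 0.1)) - offset, -_ETA_CLIP, _ETA_CLIP)
        beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    else:
        beta = np.array(beta0, dtype=float)
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(xtw @ X, xtw @ z, rcond=None)[0]
        if not np.isfinite(new).all():
            raise FloatingPointError("IRLS diverged")
        beta = new
        new_eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        delta = np.max(np.abs(new_eta - eta))
        eta = new_eta
        if delta < tol:
            break
    mu = np.exp(eta)
    return beta, mu / (1.0 + alpha * mu)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def dispersion_design(X: np.ndarray, patient_index: np.ndarray) -> np.ndarray:
    """Design matrix for dispersion estimation in the paired setting:
    patient indicator columns plus the within-patient terms (time and
    time x group).  The intercept and the between-patient group main effect
    are absorbed by the indicators; the Cox-Reid adjustment accounts for the
    many nuisance coefficients.  Keeping patient effects in this stage stops
    between-patient variability from inflating the dispersion estimate."""
    idx = np.asarray(patient_index, dtype=np.intp)
    n_pat = int(idx.max()) + 1
    dummies = np.zeros((idx.size, n_pat))
    dummies[np.arange(idx.size), idx] = 1.0
    return np.column_stack([dummies, X[:, 1], X[:, 3]])


def estimate_dispersion(gene_counts, design: np.ndarray, offsets: np.ndarray) -> float:
    """Gene-wise NB dispersion by Cox-Reid adjusted profile likelihood.

    Maximizes l(beta_hat(alpha); alpha) - 0.5 log det(X' W X) over alpha in
    [1e-8, 10] for a fixed-effects-only NB regression (the random intercept
    is ignored at this stage).  Falls back to the method-of-moments estimate
    max(lower bound, (s^2 - m)/m^2) if the profile cannot be evaluated.
    """
    y = np.asarray(gene_counts, dtype=float)
    X = np.asarray(design, dtype=float)
    o = np.asarray(offsets, dtype=float)

    warm: dict = {}

    def neg_apl(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        try:
            beta, w = _irls_nb(y, X, o, a, beta0=warm.get("beta"))
            warm["beta"] = beta
        except (FloatingPointError, np.linalg.LinAlgError):
            warm.pop("beta", None)
            return np.inf
        mu = np.exp(np.clip(X @ beta + o, -_ETA_CLIP, _ETA_CLIP))
        ll = _nb_loglik(y, mu, a).sum()
        sign, logdet = np.linalg.slogdet((X.T * w) @ X)
        if sign <= 0:
            return np.inf
        return -(ll - 0.5 * logdet)

    lo, hi = np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])
    res = optimize.minimize_scalar(neg_apl, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4})
    if res.success and np.isfinite(res.fun):
        return float(np.clip(np.exp(res.x), *ALPHA_BOUNDS))
    warnings.warn("Cox-Reid profile failed; method-of-moments fallback")
    m, s2 = y.mean(), y.var(ddof=1)
    return float(np.clip((s2 - m) / m**2 if m > 0 else 0.0, *ALPHA_BOUNDS))


def fit_dispersion_trend(base_means: np.ndarray, alphas: np.ndarray
                         ) -> Tuple[float, float]:
    """Parametric mean-dispersion trend alpha(mu) = a0 + a1/mu fitted to
    gene-wise estimates by iteratively reweighted least squares with
    gamma-style weights (1/fitted^2).  Genes hugging the optimizer bounds
    are excluded from the fit.  Returns (a0, a1), both nonnegative."""
    mu = np.asarray(base_means, dtype=float)
    a = np.asarray(alphas, dtype=float)
    use = (a > ALPHA_BOUNDS[0] * 10) & (a < ALPHA_BOUNDS[1] * 0.9) & (mu > 1e-3)
    if use.sum() < 10:
        med = float(np.median(a[a > 0])) if (a > 0).any() else 0.1
        return med, 0.0
    mu_u, a_u = mu[use], a[use]
    X = np.column_stack([np.ones_like(mu_u), 1.0 / mu_u])
    coef = np.array([np.median(a_u), 0.0])
    for _ in range(10):
        fitted = np.maximum(X @ coef, 1e-8)
        w = 1.0 / fitted**2
        xtw = X.T * w
        try:
            coef_new = np.linalg.solve(xtw @ X, xtw @ a_u)
        except np.linalg.LinAlgError:
            break
        coef_new = np.maximum(coef_new, [1e-8, 0.0])
        if np.max(np.abs(coef_new - coef)) < 1e-10:
            coef = coef_new
            break
        coef = coef_new
    return float(coef[0]), float(coef[1])


def moderate_dispersions(
    counts_matrix: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    genewise: Optional[np.ndarray] = None,
    outlier_sd: float = 2.0,
    return_uncertainty: bool = False,
):
    """Empirical-Bayes moderation of gene-wise dispersions toward a
    mean-dispersion trend (the behaviour of the standard two-stage count
    estimator): each gene's final dispersion maximizes its Cox-Reid adjusted
    profile likelihood plus a log-normal prior centered at the trend value.

    The prior variance is the excess of the robust variance of
    log(alpha_hat) - log(alpha_trend) over the approximate sampling variance
    trigamma((m - p)/2), floored at 0.25.  Genes whose gene-wise estimate
    lies more than ``outlier_sd`` robust SDs above the trend keep their
    gene-wise value (dispersion outliers are not shrunk down).
    """
    Y = np.asarray(counts_matrix, dtype=float)
    X = np.asarray(design, dtype=float)
    o = np.asarray(offsets, dtype=float)
    n_genes = Y.shape[0]
    if genewise is None:
        genewise = np.array([estimate_dispersion(Y[i], X, o)
                             for i in range(n_genes)])
    base_means = (Y / np.exp(o)[None, :]).mean(axis=1)
    a0, a1 = fit_dispersion_trend(base_means, genewise)
    trend = np.maximum(a0 + a1 / np.maximum(base_means, 1e-3), 1e-8)
    resid = np.log(genewise) - np.log(trend)
    mad = np.median(np.abs(resid - np.median(resid)))
    s_lr2 = (1.4826 * mad) ** 2
    from scipy.special import polygamma
    df = max(Y.shape[1] - X.shape[1], 3)
    sampling_var = float(polygamma(1, df / 2.0))
    prior_var = max(s_lr2 - sampling_var, 0.25)

    out = np.empty(n_genes)
    log_sd = np.empty(n_genes)
    post_var = 1.0 / (1.0 / sampling_var + 1.0 / prior_var)
    lo, hi = np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])
    for i in range(n_genes):
        if resid[i] > outlier_sd * np.sqrt(max(s_lr2, 0.25)):
            out[i] = genewise[i]
            log_sd[i] = np.sqrt(sampling_var)
            continue
        log_sd[i] = np.sqrt(post_var)
        y = Y[i]
        warm: dict = {}
        log_trend = np.log(trend[i])

        def neg_post(log_alpha: float) -> float:
            a = float(np.exp(log_alpha))
            try:
                beta, w = _irls_nb(y, X, o, a, beta0=warm.get("beta"))
                warm["beta"] = beta
            except (FloatingPointError, np.linalg.LinAlgError):
                warm.pop("beta", None)
                return np.inf
            mu = np.exp(np.clip(X @ beta + o, -_ETA_CLIP, _ETA_CLIP))
            ll = _nb_loglik(y, mu, a).sum()
            sign, logdet = np.linalg.slogdet((X.T * w) @ X)
            if sign <= 0:
                return np.inf
            return -(ll - 0.5 * logdet
                     - (log_alpha - log_trend) ** 2 / (2.0 * prior_var))

        res = optimize.minimize_scalar(neg_post, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-4})
        out[i] = (float(np.clip(np.exp(res.x), *ALPHA_BOUNDS))
                  if res.success and np.isfinite(res.fun) else genewise[i])
    if return_uncertainty:
        return out, log_sd
    return out


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

def _segment_sum(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(idx, weights=values, minlength=n)


def _find_modes(y, eta_fixed, alpha, sigma2, idx, n_pat,
                tol: float = 1e-8, max_iter: int = 100, b0=None):
    """Per-patient random-intercept modes by damped Newton; vectorized over
    patients.  Returns (b_hat, neg_curvature) where neg_curvature is
    -d2/db2 of the penalized per-patient log-density at the mode."""
    b = np.zeros(n_pat) if b0 is None else np.array(b0, dtype=float)

    def penalized(bvec):
        mu = np.exp(np.clip(eta_fixed + bvec[idx], -_ETA_CLIP, _ETA_CLIP))
        ll = _segment_sum(_nb_loglik(y, mu, alpha), idx, n_pat)
        return ll - bvec**2 / (2.0 * sigma2), mu

    obj, mu = penalized(b)
    for _ in range(max_iter):
        grad = _segment_sum((y - mu) / (1.0 + alpha * mu), idx, n_pat) - b / sigma2
        if np.max(np.abs(grad)) < tol:
            break
        curv = _segment_sum(mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2,
                            idx, n_pat) + 1.0 / sigma2
        step = np.clip(grad / curv, -4.0, 4.0)
        # per-patient backtracking; the penalized objective is strictly
        # concave in b so undamped Newton is safe except for long first steps
        scale = np.ones(n_pat)
        new_obj, new_mu = penalized(b + step)
        for _ in range(8):
            bad = new_obj < obj - 1e-10 * (1.0 + np.abs(obj))
            if not bad.any():
                break
            scale[bad] *= 0.5
            new_obj, new_mu = penalized(b + scale * step)
        b = b + scale * step
        obj, mu = new_obj, new_mu
    curv = _segment_sum(mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2,
                        idx, n_pat) + 1.0 / sigma2
    return b, curv


def laplace_loglik(beta, sigma2, y, X, offset, idx, alpha,
                   _mode_cache: Optional[dict] = None) -> float:
    """Laplace-approximated marginal log-likelihood at (beta, sigma2).

    ``_mode_cache`` is an optional dict carrying the previous call's
    random-intercept modes as a warm start for the inner Newton search;
    the returned value is identical with or without it.
    """
    n_pat = int(idx.max()) + 1
    eta_fixed = X @ beta + offset
    if sigma2 <= 0:
        mu = np.exp(np.clip(eta_fixed, -_ETA_CLIP, _ETA_CLIP))
        return float(_nb_loglik(y, mu, alpha).sum())
    b0 = _mode_cache.get("b") if _mode_cache is not None else None
    b, curv = _find_modes(y, eta_fixed, alpha, sigma2, idx, n_pat, b0=b0)
    if _mode_cache is not None:
        _mode_cache["b"] = b
    mu = np.exp(np.clip(eta_fixed + b[idx], -_ETA_CLIP, _ETA_CLIP))
    ll_data = _segment_sum(_nb_loglik(y, mu, alpha), idx, n_pat)
    g_at_mode = ll_data - b**2 / (2.0 * sigma2)
    # log integral per patient: g(b_hat) - 0.5 log(sigma2 * curv)
    return float(np.sum(g_at_mode - 0.5 * np.log(sigma2 * curv)))


def _numeric_hessian(f, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x0.size
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        ei = np.zeros(k); ei[i] = steps[i]
        for j in range(i, k):
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2.0 * f(x0) + f(x0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
    return H


def fit_gene(
    y,
    X: np.ndarray,
    offset: np.ndarray,
    patient_index: np.ndarray,
    alpha: float,
    seed: int = 0,
    n_restarts: int = 2,
) -> GeneFit:
    """Fit the NB random-intercept model for one gene with dispersion fixed.

    Maximizes the Laplace marginal likelihood over (beta, log sigma) with
    L-BFGS-B, compares against the explicit sigma = 0 boundary (an ordinary
    fixed-effects NB regression), and reports the better of the two.  The
    coefficient covariance V is the inverse observed-information block for
    beta at the optimum (conditional on the variance parameter).  On
    non-convergence the search restarts from seed-perturbed starting values.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    idx = np.asarray(patient_index, dtype=np.intp)
    if alpha <= 0:
        raise ValueError("dispersion must be positive")
    n_pat = int(idx.max()) + 1
    counts_per_pat = np.bincount(idx, minlength=n_pat)
    if (counts_per_pat >= 2).sum() < 3:
        raise ValueError("need at least 3 patients with both visits")
    p = X.shape[1]

    # sigma = 0 boundary: plain fixed-effects fit
    try:
        beta_fix, w_fix = _irls_nb(y, X, offset, alpha)
        ll_fix = laplace_loglik(beta_fix, 0.0, y, X, offset, idx, alpha)
    except (FloatingPointError, np.linalg.LinAlgError):
        beta_fix, w_fix, ll_fix = np.zeros(p), None, -np.inf

    cache: dict = {}

    def nll(theta):
        val = laplace_loglik(theta[:p], float(np.exp(2.0 * theta[p])),
                             y, X, offset, idx, alpha, _mode_cache=cache)
        return -val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    starts = [np.concatenate([beta_fix, [np.log(0.5)]])]
    for _ in range(n_restarts):
        starts.append(starts[0] + rng.normal(scale=0.2, size=p + 1))
    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(10.0))]

    best = None
    for start in starts:
        cache.clear()
        res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 200})
        ok = res.success or (np.isfinite(res.fun)
                             and np.max(np.abs(res.jac)) < 1e-2)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if ok:
            break

    converged = best is not None and np.isfinite(best.fun)
    use_boundary = (not converged) or (ll_fix >= -best.fun - 1e-6)

    if use_boundary:
        if w_fix is None:
            return GeneFit(np.full(p, np.nan), np.full((p, p), np.nan),
                           np.nan, alpha, -np.inf, False)
        info = (X.T * w_fix) @ X   # expected information of the NB GLM
        vcov = np.linalg.inv(info)
        return GeneFit(beta_fix, vcov, 0.0, alpha, ll_fix, True)

    beta_hat = best.x[:p]
    sigma2_hat = float(np.exp(2.0 * best.x[p]))
    ll_hat = -float(best.fun)
    well_converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-2)

    def beta_nll(b):
        return -laplace_loglik(b, sigma2_hat, y, X, offset, idx, alpha,
                               _mode_cache=cache)

    H = _numeric_hessian(beta_nll, beta_hat)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return GeneFit(beta_hat, np.full((p, p), np.nan), sigma2_hat, alpha,
                       ll_hat, False)
    if not np.isfinite(vcov).all() or (np.diag(vcov) <= 0).any():
        return GeneFit(beta_hat, np.full((p, p), np.nan), sigma2_hat, alpha,
                       ll_hat, False)
    vcov = 0.5 * (vcov + vcov.T)
    return GeneFit(beta_hat, vcov, sigma2_hat, alpha, ll_hat, well_converged)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

_TERM_COLUMNS = {"time": [1], "group": [2], "time:group": [3]}
_TERM_RELATIVES = {"time": [3], "group": [3], "time:group": []}


def _joint_wald(beta: np.ndarray, V: np.ndarray, cols: Sequence[int]) -> float:
    if not cols:
        return 0.0
    b = beta[list(cols)]
    Vs = V[np.ix_(cols, cols)]
    try:
        return float(b @ np.linalg.solve(Vs, b))
    except np.linalg.LinAlgError:
        return np.nan


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(9)


def _chi2_tail(stat: float, df: int, logsd: float) -> float:
    """Upper chi-square tail, optionally averaged over a log-normal
    uncertainty of the Wald variance: with log V-hat erring by
    eta ~ N(0, logsd^2), p = E_eta[ P(chi2_df > stat * exp(-eta)) ]."""
    if logsd <= 0:
        return float(chi2.sf(stat, df))
    scaled = stat * np.exp(-np.sqrt(2.0) * logsd * _GH_NODES)
    return float(np.sum(_GH_WEIGHTS * chi2.sf(scaled, df)) / np.sqrt(np.pi))


def dispersion_sensitivity(fit: GeneFit, X: np.ndarray, offset: np.ndarray
                           ) -> float:
    """Approximate elasticity of the Wald variance to the dispersion,
    d log V / d log alpha ~ mean over observations of alpha*mu/(1+alpha*mu)
    at the fitted means."""
    mu = np.exp(np.clip(X @ fit.beta + offset, -_ETA_CLIP, _ETA_CLIP))
    return float(np.mean(fit.alpha * mu / (1.0 + fit.alpha * mu)))


def wald_type2(fit: GeneFit, model_terms: Iterable[str] = TERMS,
               dispersion_logsd: float = 0.0
               ) -> Dict[str, Tuple[float, int, float]]:
    """Type-2 Wald chi-square per term.

    Marginality is respected by the difference construction: the statistic
    for a term is the joint Wald test of the term together with its
    containing interactions minus the joint test of those interactions
    alone.  For the interaction itself (no containing terms) this is the
    familiar (beta/SE)^2.  Singular covariance blocks flag the term's p as
    missing (NaN).

    ``dispersion_logsd`` is the SD of log V-hat induced by the uncertainty
    of the plug-in dispersion (elasticity x posterior log-alpha SD); when
    positive, the chi-square tail is averaged over that uncertainty, which
    removes the far-tail anti-conservatism of treating the estimated
    dispersion as known.  The statistic itself is unchanged.
    """
    if not fit.converged or not np.isfinite(fit.vcov).all():
        raise ValueError("Wald tests need a converged fit with covariance")
    out: Dict[str, Tuple[float, int, float]] = {}
    for term in model_terms:
        cols = _TERM_COLUMNS[term]
        rel = _TERM_RELATIVES[term]
        w_full = _joint_wald(fit.beta, fit.vcov, rel + cols)
        w_rel = _joint_wald(fit.beta, fit.vcov, rel)
        stat = w_full - w_rel
        df = len(cols)
        if not np.isfinite(stat):
            out[term] = (np.nan, df, np.nan)
            continue
        stat = max(stat, 0.0)
        out[term] = (stat, df, _chi2_tail(stat, df, dispersion_logsd))
    fit.wald = out
    return out


def predict_with_ci(fit: GeneFit, new_design_rows, offset=0.0,
                    conf_level: float = 0.95):
    """Fitted mean and Wald CI on the response scale for new design rows
    (fixed effects only, random intercept at 0).

    eta = X beta, var(eta) = diag(X V X'); CI = exp(eta +/- z sqrt(var))
    times exp(offset).
    """
    if not fit.converged:
        raise ValueError("prediction requires a converged fit")
    Xn = np.atleast_2d(np.asarray(new_design_rows, dtype=float))
    if Xn.shape[1] != fit.beta.size:
        raise ValueError(
            f"design rows have {Xn.shape[1]} columns, model has {fit.beta.size}"
        )
    from scipy.stats import norm
    z = norm.ppf(0.5 + conf_level / 2.0)
    eta = Xn @ fit.beta
    var = np.einsum("ij,jk,ik->i", Xn, fit.vcov, Xn)
    var = np.maximum(var, 0.0)
    scale = np.exp(np.asarray(offset, dtype=float))
    fitted = np.exp(eta) * scale
    lo = np.exp(eta - z * np.sqrt(var)) * scale
    hi = np.exp(eta + z * np.sqrt(var)) * scale
    return pd.DataFrame({"fitted": fitted, "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# whole-matrix driver
# ---------------------------------------------------------------------------

def fit_all(
    data: LongitudinalCountData,
    formula_variant: str = "time*medication",
    fdr: float = 0.05,
    min_count: float = 10,
    min_prop: float = 0.7,
    apply_filter: bool = True,
    dispersion_moderation: bool = True,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run filter -> dispersion -> pseudo-count -> mixed fit -> type-2 Wald
    per gene; Storey q-values per term across genes; per-arm log2 fold
    change over time from the coefficients (arm 0: beta1 * log2 e, arm 1:
    (beta1 + beta3) * log2 e).

    Dispersions are gene-wise Cox-Reid estimates shrunk toward a
    mean-dispersion trend (``dispersion_moderation=False`` keeps the raw
    gene-wise values); the paired dispersion design includes patient
    indicators so between-patient variability is not absorbed into alpha.

    ``formula_variant`` names the grouping covariate carried in
    metadata['group']: 'time*medication' for the two-arm model or
    'time*response' for the per-drug responder model; the design matrix is
    identical, only the interpretation differs.
    """
    if formula_variant not in ("time*medication", "time*response"):
        raise ValueError(f"unknown formula variant {formula_variant!r}")
    paired = data.paired_subset()
    n_pairs = paired.metadata["patient_id"].nunique()
    if n_pairs < 3:
        raise ValueError("fewer than 3 complete pairs; refusing to fit")
    X, idx = paired.design()
    offsets = paired.offsets

    counts = paired.counts
    if apply_filter:
        kept = filter_low_expressed(counts, paired.metadata["group"],
                                    min_count=min_count, min_prop=min_prop)
        counts = counts.loc[kept]
    if counts.shape[0] == 0:
        warnings.warn("no genes left after filtering; empty results")
        return _empty_results()

    genes = list(counts.index)
    raw = counts.to_numpy(dtype=float)
    disp_X = dispersion_design(X, idx)

    genewise = np.array([estimate_dispersion(raw[i], disp_X, offsets)
                         for i in range(len(genes))])
    from scipy.special import polygamma
    sampling_sd = float(np.sqrt(polygamma(
        1, max(raw.shape[1] - disp_X.shape[1], 3) / 2.0)))
    if dispersion_moderation and len(genes) >= 20:
        alphas, alpha_logsd = moderate_dispersions(
            raw, disp_X, offsets, genewise=genewise, return_uncertainty=True)
    else:
        alphas = genewise
        alpha_logsd = np.full(len(genes), sampling_sd)

    def one_gene(i: int) -> dict:
        row = raw[i]
        alpha = float(alphas[i])
        y = pseudo_count_adjust(row)
        rec: dict = {"alpha": alpha}
        try:
            fit = fit_gene(y, X, offsets, idx, alpha, seed=seed)
        except (ValueError, np.linalg.LinAlgError):
            fit = None
        if fit is None or not fit.converged:
            rec.update({"converged": False})
            return rec
        rec.update({
            "converged": True, "sigma2": fit.sigma2, "loglik": fit.loglik,
            "log2fc_arm0": fit.beta[1] * _LOG2E,
            "log2fc_arm1": (fit.beta[1] + fit.beta[3]) * _LOG2E,
        })
        logsd = dispersion_sensitivity(fit, X, offsets) * float(alpha_logsd[i])
        for term, (stat, df, p) in wald_type2(
                fit, dispersion_logsd=logsd).items():
            key = term.replace(":", "_x_")
            rec[f"chisq_{key}"] = stat
            rec[f"p_{key}"] = p
        return rec

    if n_jobs != 1:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=n_jobs)(delayed(one_gene)(i)
                                          for i in range(len(genes)))
    else:
        records = [one_gene(i) for i in range(len(genes))]

    results = pd.DataFrame(records, index=pd.Index(genes, name="gene"))
    for key in ("time", "group", "time_x_group"):
        col = f"p_{key}"
        if col not in results:
            results[col] = np.nan
        q = np.full(len(results), np.nan)
        ok = results[col].notna().to_numpy()
        if ok.any():
            q[ok] = qvalues(results.loc[ok, col].to_numpy())
        results[f"q_{key}"] = q
    results["label"] = classify_interaction_genes(results, fdr=fdr)
    return results


def _empty_results() -> pd.DataFrame:
    cols = ["alpha", "converged", "sigma2", "loglik", "log2fc_arm0",
            "log2fc_arm1"]
    for key in ("time", "group", "time_x_group"):
        cols += [f"chisq_{key}", f"p_{key}", f"q_{key}"]
    cols.append("label")
    return pd.DataFrame(columns=cols, index=pd.Index([], name="gene"))


def classify_interaction_genes(results: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Label genes from the q-values and per-arm fold changes.

    Significant interaction (q < fdr) -> 'drug1_dominant' or
    'drug2_dominant' by the larger absolute log2 fold change over time;
    otherwise significant time effect -> 'time_shared'; else 'unclassified'.
    """
    q_int = results.get("q_time_x_group")
    q_time = results.get("q_time")
    labels = []
    for gene in results.index:
        qi = q_int.loc[gene] if q_int is not None else np.nan
        qt = q_time.loc[gene] if q_time is not None else np.nan
        if np.isfinite(qi) and qi < fdr:
            a0 = abs(results.at[gene, "log2fc_arm0"])
            a1 = abs(results.at[gene, "log2fc_arm1"])
            labels.append("drug1_dominant" if a0 >= a1 else "drug2_dominant")
        elif np.isfinite(qt) and qt < fdr:
            labels.append("time_shared")
        else:
            labels.append("unclassified")
    return pd.Series(labels, index=results.index, name="label")
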