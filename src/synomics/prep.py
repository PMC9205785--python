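"""Count-matrix normalization and filtering.

All operations act on a genes x samples matrix carried as a pandas
DataFrame (rows indexed by gene id, columns by sample id).  Filters return
the retained gene index so they can be composed; every filter is
idempotent.  The variance-stabilizing transform used in the original
processing chain is replaced by an explicit log transform (``log_norm``)
-- downstream consumers (CV filter, deconvolution scores, classifier
features) need only a monotone variance-damping transform.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd


class NormalizationError(ValueError):
    pass


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    return pd.DataFrame(np.asarray(counts, dtype=float))


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j: sf_j = median over genes g of counts[g, j] / geomean_g,
    where geomean_g is the geometric mean of gene g across samples and genes
    with any zero count are excluded from the median.
    """
    counts = _as_frame(counts)
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise NormalizationError("negative counts")
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError("no gene with all-positive counts")
    pos = x[all_pos]
    log_geomean = np.log(pos).mean(axis=1)
    sf = np.exp(np.median(np.log(pos) - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def loq_filter(counts: pd.DataFrame, loq_per_sample, min_fraction: float = 0.10) -> pd.Index:
    """Keep genes exceeding the per-sample lower level of quantitation in
    strictly more than ``min_fraction`` of samples."""
    counts = _as_frame(counts)
    loq = np.asarray(loq_per_sample, dtype=float)
    if loq.shape != (counts.shape[1],):
        raise ValueError(
            f"loq_per_sample has length {loq.size}, expected {counts.shape[1]}"
        )
    if (loq <= 0).any():
        raise ValueError("LOQ values must be positive")
    frac = (counts.to_numpy(dtype=float) > loq[None, :]).mean(axis=1)
    return counts.index[frac > min_fraction]


def cv_filter(transformed_expr: pd.DataFrame, cv_cutoff: float = 0.075) -> pd.Index:
    """Keep genes with coefficient of variation (sd/mean) strictly above the
    cutoff.  Zero-mean genes are excluded with a warning."""
    expr = _as_frame(transformed_expr)
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    zero = mean == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-mean genes excluded from CV filter")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(zero, 0.0, sd / np.where(zero, 1.0, np.abs(mean)))
    return expr.index[(cv > cv_cutoff) & ~zero]


def filter_low_expressed(
    counts: pd.DataFrame,
    group_labels,
    min_count: float = 10,
    min_prop: float = 0.7,
) -> pd.Index:
    """Remove low-expression genes before model fitting.

    Counts are rescaled to the median library size; a gene is kept iff the
    rescaled count reaches ``min_count`` in at least
    ceil(min_prop * smallest group size) samples.
    """
    counts = _as_frame(counts)
    labels = pd.Series(list(group_labels), index=counts.columns)
    sizes = labels.value_counts()
    if sizes.empty or (sizes < 1).any():
        raise ValueError("every group must contain at least one sample")
    n_needed = math.ceil(min_prop * sizes.min())
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    scaled = counts.to_numpy(dtype=float) * (np.median(lib) / lib)[None, :]
    keep = (scaled >= min_count).sum(axis=1) >= n_needed
    return counts.index[keep]


def log_norm(counts: pd.DataFrame, size_factors=None, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudo), elementwise."""
    counts = _as_frame(counts)
    if size_factors is None:
        sf = np.ones(counts.shape[1])
    else:
        sf = np.asarray(size_factors, dtype=float)
        if (sf <= 0).any():
            raise NormalizationError("size factors must be positive")
    x = counts.to_numpy(dtype=float) / sf[None, :] + pseudo
    return pd.DataFrame(np.log2(x), index=counts.index, columns=counts.columns)


def remove_correlated(feature_matrix: pd.DataFrame, cutoff: float = 0.9) -> pd.Index:
    """Greedy removal of highly correlated features.

    ``feature_matrix`` is samples x features.  While any absolute pairwise
    Pearson correlation exceeds the cutoff, the member of the worst pair with
    the larger mean absolute correlation to all remaining features is dropped
    (ties broken by removing the lexicographically later id).  Constant
    features have correlation treated as 0 and are always retained.
    """
    fm = _as_frame(feature_matrix)
    if fm.shape[1] < 2:
        return fm.columns
    x = fm.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 0.0)
    abs_corr = np.abs(corr)
    names = list(fm.columns)
    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = np.where(alive)[0]
        block = abs_corr[np.ix_(sub, sub)]
        mx = block.max(initial=0.0)
        if mx <= cutoff:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(block), block.shape)
        i, j = sub[i_loc], sub[j_loc]
        mean_i = abs_corr[i, sub].sum() / max(len(sub) - 1, 1)
        mean_j = abs_corr[j, sub].sum() / max(len(sub) - 1, 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = i if str(names[i]) > str(names[j]) else j
        alive[drop] = False
    return fm.columns[alive]


def top_variance_fraction(
    transformed_expr: pd.DataFrame,
    fraction: float = 0.10,
    coding_mask=None,
) -> pd.Index:
    """Keep the top ``fraction`` of (protein-coding) genes by expression
    variance; ceil(fraction * n) genes, ties at the threshold broken by id."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    expr = _as_frame(transformed_expr)
    if coding_mask is not None:
        mask = np.asarray(coding_mask, dtype=bool)
        if mask.shape != (expr.shape[0],):
            raise ValueError("coding mask length mismatch")
        expr = expr.loc[expr.index[mask]]
    if expr.shape[0] == 0:
        raise ValueError("no coding genes to rank")
    var = expr.var(axis=1, ddof=1) if expr.shape[1] > 1 else pd.Series(0.0, index=expr.index)
    n_keep = math.ceil(fraction * expr.shape[0])
    order = sorted(expr.index, key=lambda g: (-var[g], str(g)))
    kept = set(order[:n_keep])
    return expr.index[[g in kept for g in expr.index]]
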