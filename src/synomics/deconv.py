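"""Marker-based deconvolution of bulk expression and patient stratification.

A cell population's score for a sample is the arithmetic mean of its marker
genes' transformed expression -- the published marker-counting approach.
Patients are stratified rich/poor per population at the cohort median
(strictly above -> rich), labels that are invariant to any strictly
monotone transform of the expression matrix.  ``module_score`` implements
gene-set scoring against expression-bin-matched control genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

DEFAULT_POPULATIONS = ("B", "T_CD8", "NK", "monocyte_macrophage", "mDC",
                       "neutrophil", "endothelial", "fibroblast")


@dataclass
class MarkerSet:
    """Population name -> marker gene ids.  Lists must be nonempty and
    free of within-population duplicates."""

    populations: Dict[str, List[str]]
    provenance: str = "user"

    def __post_init__(self):
        for pop, genes in self.populations.items():
            if not genes:
                raise ValueError(f"population {pop!r} has no markers")
            if len(set(genes)) != len(genes):
                raise ValueError(f"population {pop!r} has duplicate markers")

    @classmethod
    def from_dict(cls, d: dict, provenance: str = "config") -> "MarkerSet":
        return cls({str(k): [str(g) for g in v] for k, v in d.items()}, provenance)

    @classmethod
    def default(cls) -> "MarkerSet":
        """Surrogate literature-derived marker lists shipped with the
        package (editable YAML under synomics/data)."""
        import yaml
        from importlib.resources import files
        raw = yaml.safe_load(
            files("synomics.data").joinpath("markers_default.yaml").read_text())
        return cls.from_dict(raw, provenance="synomics default (surrogate)")


def population_scores(transformed_expr: pd.DataFrame, markers: MarkerSet) -> pd.DataFrame:
    """Samples x populations score table: per-sample arithmetic mean of each
    population's marker genes.  Markers absent from the matrix are dropped
    with a warning; a population with no marker present yields NaN."""
    out = {}
    for pop, genes in markers.populations.items():
        present = [g for g in genes if g in transformed_expr.index]
        absent = len(genes) - len(present)
        if absent:
            warnings.warn(f"{pop}: {absent} marker(s) absent from the matrix")
        if not present:
            out[pop] = pd.Series(np.nan, index=transformed_expr.columns)
        else:
            out[pop] = transformed_expr.loc[present].mean(axis=0)
    return pd.DataFrame(out)


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """Rich/poor labels at the cohort median: rich iff score strictly above
    the median (a score equal to the median is poor)."""
    s = pd.Series(scores).astype(float)
    if s.size < 2:
        raise ValueError("need at least two patients to stratify")
    med = s.median()
    if (s == s.iloc[0]).all():
        warnings.warn("all scores tied; every patient labeled poor")
    return pd.Series(np.where(s > med, "rich", "poor"), index=s.index, name=s.name)


def combine_strata(bcell_label: Optional[str], myeloid_label: Optional[str]) -> Optional[str]:
    """Cross B cell and macrophage/mDC strata, e.g. ('poor','rich') ->
    'Bpoor_MACrich'.  Missing input yields a missing combined label."""
    if bcell_label is None or myeloid_label is None:
        return None
    for lab in (bcell_label, myeloid_label):
        if lab not in ("rich", "poor"):
            raise ValueError(f"label must be rich/poor, got {lab!r}")
    return f"B{bcell_label}_MAC{myeloid_label}"


@dataclass
class StratifiedCohort:
    """Per-patient deconvolution scores, rich/poor labels, combined stratum
    and response label; the input to the association statistics."""

    scores: pd.DataFrame
    labels: pd.DataFrame = field(init=False)
    combined: pd.Series = field(init=False)
    response: Optional[pd.Series] = None

    def __post_init__(self):
        self.labels = self.scores.apply(stratify_by_median, axis=0)
        if {"B", "monocyte_macrophage"} <= set(self.labels.columns):
            self.combined = pd.Series(
                [combine_strata(b, m) for b, m in
                 zip(self.labels["B"], self.labels["monocyte_macrophage"])],
                index=self.labels.index, name="combined",
            )
        else:
            self.combined = pd.Series(None, index=self.labels.index, dtype=object)


def module_score(
    transformed_expr: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Gene-set score per sample against expression-matched controls.

    Genes are binned by average expression into ``n_bins`` equal-frequency
    bins; for each set gene, ``n_ctrl`` control genes are drawn from its bin
    (without replacement where the bin allows, otherwise with replacement).
    The score is mean(set genes) - mean(control genes), per sample.
    """
    genes = [g for g in gene_set if g in transformed_expr.index]
    if not genes:
        raise ValueError("gene set has no overlap with the expression matrix")
    rng = np.random.default_rng(seed)
    avg = transformed_expr.mean(axis=1)
    # equal-frequency bins over all genes
    ranks = avg.rank(method="first")
    bins = np.ceil(ranks / len(avg) * n_bins).astype(int).clip(1, n_bins)
    by_bin = {b: list(transformed_expr.index[bins == b]) for b in range(1, n_bins + 1)}
    ctrl_genes: list = []
    for g in genes:
        pool = by_bin[bins[g]]
        if len(pool) >= n_ctrl:
            picked = rng.choice(len(pool), size=n_ctrl, replace=False)
        else:
            picked = rng.choice(len(pool), size=n_ctrl, replace=True)
        ctrl_genes.extend(pool[i] for i in picked)
    set_mean = transformed_expr.loc[genes].mean(axis=0)
    ctrl_mean = transformed_expr.loc[ctrl_genes].mean(axis=0)
    return (set_mean - ctrl_mean).rename("module_score")
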