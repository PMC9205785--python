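"""Readers and writers for the formats the pipeline exchanges.

Counts travel as genes x samples TSV/CSV (header row = sample ids) or
MatrixMarket with companion row/column id files; metadata as CSV with
mandated column names; gene sets as GMT; marker sets and run configuration
as YAML.  Validation is strict: duplicate ids, negative entries and
unknown config keys are errors, not warnings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

METADATA_COLUMNS = ("patient_id", "visit_month", "tjc", "sjc", "ptga", "ehga",
                    "medication", "cd20", "cd3", "cd138", "cd68l", "cd68sl",
                    "krenn")


class ParseError(ValueError):
    pass


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicated gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicated sample id {dup!r}")
    x = df.to_numpy()
    if not np.issubdtype(x.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(f"non-numeric entry at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    neg = np.argwhere(x < 0)
    if len(neg):
        r, c = neg[0]
        raise ParseError(f"negative count at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    return df


def read_counts(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a genes x samples count matrix (tsv, csv or mtx).

    MTX input expects ``<stem>.rows.txt`` / ``<stem>.cols.txt`` id files
    beside the matrix.
    """
    path = Path(path)
    fmt = fmt or {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".mtx": "mtx"}.get(path.suffix.lower())
    if fmt not in ("tsv", "csv", "mtx"):
        raise ValueError(f"unsupported counts format {fmt!r} for {path}")
    if fmt == "mtx":
        base = str(path.with_suffix(""))
        rows = _read_ids(Path(base + ".rows.txt"))
        cols = _read_ids(Path(base + ".cols.txt"))
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return _validate_counts(df)


def _read_ids(path: Path) -> List[str]:
    if not path.exists():
        raise FileNotFoundError(f"MTX companion id file missing: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(df: pd.DataFrame, path, fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mmwrite(str(path), csr_matrix(df.to_numpy()))
        base = str(path.with_suffix(""))
        Path(base + ".rows.txt").write_text("\n".join(map(str, df.index)) + "\n")
        Path(base + ".cols.txt").write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",")


def read_metadata(path, required=("patient_id",)) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"metadata missing column(s): {', '.join(missing)}")
    return df


def read_gene_sets(path_gmt) -> Dict[str, List[str]]:
    """Parse a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``; empty sets and
    duplicate set names are errors; gene order is preserved."""
    sets: Dict[str, List[str]] = {}
    for lineno, line in enumerate(Path(path_gmt).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path_gmt}:{lineno}: expected name, description "
                             "and at least one gene")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if not genes:
            raise ParseError(f"{path_gmt}:{lineno}: set {name!r} is empty")
        if name in sets:
            raise ParseError(f"{path_gmt}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
    return sets


def read_marker_yaml(path) -> Dict[str, List[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError("marker YAML must map population -> list of genes")
    return {str(k): [str(g) for g in v] for k, v in raw.items()}


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class StageParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_count: float = 10
    min_prop: float = 0.7
    cv_cutoff: float = 0.075
    loq_min_fraction: float = 0.10
    correlation_cutoff: float = 0.9
    top_variance: float = 0.10
    fdr: float = 0.05
    pathotype_ruleset: str = "figure"
    formula_variant: str = "time*medication"
    k_outer: int = 10
    k_inner: int = 10


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    counts: Optional[str] = None
    metadata: Optional[str] = None
    markers: Optional[str] = None
    gene_sets: Optional[str] = None
    out_dir: str = "results"
    seed: int = Field(default=0, ge=0)
    threads: int = Field(default=1, ge=1)
    stages: List[str] = Field(default_factory=lambda: ["simulate", "fit"])
    simulation: Dict = Field(default_factory=dict)
    params: StageParams = Field(default_factory=StageParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
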