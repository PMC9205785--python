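"""Stage orchestration: run configured stages in dependency order, write
artifacts with a content-hash manifest, and log provenance as JSON lines.
All randomness derives from the single config seed."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List

import pandas as pd

from synomics import io as sio
from synomics.clinical import BiopsyScores, classify_pathotype
from synomics.deconv import MarkerSet, StratifiedCohort, population_scores
from synomics.glmm import fit_all
from synomics.prep import log_norm, size_factors_median_ratio
from synomics.simulate import SimulationConfig, generate_counts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    def __init__(self, config: sio.RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: Dict[str, str] = {}
        self._log_path = self.out / "run_log.jsonl"

    def log(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "seed": self.config.seed,
               "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
        with open(self._log_path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")

    def register(self, path: Path) -> None:
        self.manifest[str(path.relative_to(self.out))] = _sha256(path)

    def write_manifest(self) -> Path:
        path = self.out / "manifest.json"
        sio.write_json(self.manifest, path)
        return path


def run_pipeline(config: sio.RunConfig) -> Dict[str, str]:
    """Execute the requested stages; returns the artifact manifest.
    Stage failures raise after the partial manifest is written."""
    run = PipelineRun(config)
    data = None
    try:
        for stage in config.stages:
            if stage == "simulate":
                sim = SimulationConfig(seed=config.seed, **config.simulation)
                data, truth = generate_counts(sim)
                sio.write_counts(data.counts, run.out / "counts.tsv")
                data.metadata.to_csv(run.out / "metadata.csv")
                truth.beta.to_csv(run.out / "ground_truth_beta.csv")
                truth.alpha.to_csv(run.out / "ground_truth_alpha.csv")
                for f in ("counts.tsv", "metadata.csv", "ground_truth_beta.csv",
                          "ground_truth_alpha.csv"):
                    run.register(run.out / f)
                run.log("simulate", n_genes=sim.n_genes, n_patients=sim.n_patients)
            elif stage == "fit":
                if data is None:
                    data = _load_counts(config)
                results = fit_all(data,
                                  formula_variant=config.params.formula_variant,
                                  fdr=config.params.fdr, seed=config.seed,
                                  n_jobs=config.threads)
                results.to_csv(run.out / "glmm_results.tsv", sep="\t")
                run.register(run.out / "glmm_results.tsv")
                run.log("fit", n_genes=len(results),
                        fdr=config.params.fdr,
                        formula=config.params.formula_variant)
            elif stage == "pathotype":
                meta = sio.read_metadata(config.metadata,
                                         required=("patient_id", "cd20",
                                                   "cd138", "cd68sl"))
                labels = []
                for _, row in meta.iterrows():
                    scores = BiopsyScores(
                        **{k: (None if pd.isna(row.get(k)) else int(row[k]))
                           for k in ("cd20", "cd3", "cd138", "cd68l", "cd68sl",
                                     "krenn") if k in row})
                    labels.append(classify_pathotype(
                        scores, config.params.pathotype_ruleset).value)
                out = meta[["patient_id"]].assign(pathotype=labels)
                out.to_csv(run.out / "pathotypes.csv", index=False)
                run.register(run.out / "pathotypes.csv")
                run.log("pathotype", n=len(out),
                        ruleset=config.params.pathotype_ruleset)
            elif stage == "deconvolve":
                counts = sio.read_counts(config.counts)
                sf = size_factors_median_ratio(counts)
                expr = log_norm(counts, sf)
                markers = (MarkerSet.from_dict(sio.read_marker_yaml(config.markers))
                           if config.markers else MarkerSet.default())
                scores = population_scores(expr, markers)
                cohort = StratifiedCohort(scores)
                scores.to_csv(run.out / "deconvolution_scores.csv")
                cohort.labels.to_csv(run.out / "deconvolution_labels.csv")
                for f in ("deconvolution_scores.csv", "deconvolution_labels.csv"):
                    run.register(run.out / f)
                run.log("deconvolve", populations=list(scores.columns))
            else:
                raise ValueError(f"unknown stage {stage!r}")
    finally:
        run.write_manifest()
        run.register(run.out / "manifest.json")
    return run.manifest


def _load_counts(config: sio.RunConfig):
    from synomics.glmm import LongitudinalCountData
    if not config.counts or not config.metadata:
        raise ValueError("fit stage needs counts and metadata paths")
    counts = sio.read_counts(config.counts)
    meta = sio.read_metadata(config.metadata,
                             required=("patient_id", "time", "group",
                                       "library_size"))
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    else:
        meta.index = counts.columns
    missing = set(counts.columns) ^ set(meta.index)
    if missing:
        raise ValueError(f"sample ids disagree between counts and metadata: "
                         f"{sorted(missing)[:5]}")
    return LongitudinalCountData(counts, meta.loc[counts.columns])
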