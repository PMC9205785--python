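"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators sharing one root seed (independent streams are derived by
fixed offsets, so enlarging the gene panel never perturbs the clinical
simulation):

* ``generate_counts`` -- paired longitudinal NB counts per gene with
  patient random intercepts, a two-arm design with 0/16-week visits and
  log library-size offsets; ground truth (all coefficients, dispersions,
  intercepts, library sizes) is returned for recovery tests.
* ``generate_histology`` -- semiquantitative biopsy scores (0-4, Krenn
  0-9) obtained by thresholding a shared per-patient latent inflammation
  factor into equal-probability ordinal bins.
* ``generate_cdai_course`` -- CDAI trajectories over months 0-4 with
  arm/stratum-specific slopes, patient intercepts and noise, clamped to
  0-76 and back-filled into components that sum exactly to the total.

Defaults mirror the trial's scale: 133 baseline patients of whom 44 carry
a paired 16-week biopsy, two medications, and ~2% of genes carrying a
nonzero time x medication interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from synomics.glmm import LongitudinalCountData

_STREAM_COUNTS = 0
_STREAM_HISTOLOGY = 1
_STREAM_CDAI = 2


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and distributional parameters for the generators.

    Library-size and dispersion distributions are conventions (lognormal),
    as no empirical distribution is prescribed; see the methods note.
    """

    n_patients: int = 133
    n_paired: int = 44
    n_genes: int = 2000
    timepoints: Tuple[int, int] = (0, 16)
    medications: Tuple[str, str] = ("rituximab", "tocilizumab")
    frac_interaction_genes: float = 0.02
    frac_time_genes: float = 0.0
    effect_size_sd: float = 1.0
    fixed_effect_magnitude: Optional[float] = None  # |beta3| fixed, random sign
    sigma_b: float = 0.5
    base_mean_log_params: Tuple[float, float] = (3.0, 1.5)
    dispersion_lognormal_params: Tuple[float, float] = (-1.5, 0.5)
    libsize_lognormal_params: Tuple[float, float] = (16.1, 0.35)
    seed: int = 0

    def __post_init__(self):
        if self.n_paired > self.n_patients:
            raise ConfigurationError("n_paired cannot exceed n_patients")
        if min(self.n_patients, self.n_paired, self.n_genes) < 1:
            raise ConfigurationError("counts must be positive integers")
        if not (0.0 <= self.frac_interaction_genes <= 1.0):
            raise ConfigurationError("frac_interaction_genes must lie in [0, 1]")
        if not (0.0 <= self.frac_time_genes <= 1.0):
            raise ConfigurationError("frac_time_genes must lie in [0, 1]")
        if self.sigma_b < 0 or self.effect_size_sd < 0:
            raise ConfigurationError("scale parameters must be nonnegative")
        if self.dispersion_lognormal_params[1] < 0 or self.libsize_lognormal_params[1] < 0:
            raise ConfigurationError("lognormal sdlog must be nonnegative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Generating parameters stored alongside every simulated dataset."""

    beta: pd.DataFrame          # genes x (beta0, beta1, beta2, beta3)
    alpha: pd.Series            # per-gene dispersion
    random_intercepts: pd.DataFrame  # genes x patients
    library_sizes: pd.Series    # per sample
    arm: pd.Series              # per patient (0/1)
    interaction_genes: pd.Index


def generate_counts(config: SimulationConfig
                    ) -> Tuple[LongitudinalCountData, GroundTruth]:
    """Draw NB counts under the longitudinal mixed model.

    Y_ijg ~ NB(mean = exp(o_ij + beta0 + beta1 t + beta2 arm + beta3 t*arm
    + b_gi), dispersion alpha_g), with o_ij = log(L_ij / median L), t and
    arm coded {0,1}.  Deterministic given the config seed.
    """
    rng = config.rng(_STREAM_COUNTS)
    n_pat, n_paired, n_genes = config.n_patients, config.n_paired, config.n_genes
    patients = [f"P{i:04d}" for i in range(n_pat)]
    arm = np.tile([0, 1], (n_pat + 1) // 2)[:n_pat]

    sample_patient, sample_time = [], []
    for i in range(n_pat):
        sample_patient.append(i); sample_time.append(0)
        if i < n_paired:
            sample_patient.append(i); sample_time.append(1)
    sample_patient = np.asarray(sample_patient)
    sample_time = np.asarray(sample_time, dtype=float)
    n_samples = sample_patient.size
    sample_ids = [
        f"{patients[p]}_wk{config.timepoints[int(t)]}"
        for p, t in zip(sample_patient, sample_time)
    ]

    meanlog_l, sdlog_l = config.libsize_lognormal_params
    lib = rng.lognormal(meanlog_l, sdlog_l, size=n_samples)
    if (lib <= 0).any():
        raise ConfigurationError("nonpositive library size drawn")
    offsets = np.log(lib / np.median(lib))

    meanlog_b0, sdlog_b0 = config.base_mean_log_params
    beta0 = rng.normal(meanlog_b0, sdlog_b0, size=n_genes)
    beta1 = np.zeros(n_genes)
    beta2 = np.zeros(n_genes)
    beta3 = np.zeros(n_genes)
    n_time = int(round(config.frac_time_genes * n_genes))
    if n_time:
        beta1[rng.choice(n_genes, size=n_time, replace=False)] = (
            rng.normal(0.0, config.effect_size_sd, size=n_time))
    n_int = int(round(config.frac_interaction_genes * n_genes))
    int_idx = rng.choice(n_genes, size=n_int, replace=False) if n_int else np.array([], dtype=int)
    if n_int:
        if config.fixed_effect_magnitude is not None:
            beta3[int_idx] = (config.fixed_effect_magnitude
                              * rng.choice([-1.0, 1.0], size=n_int))
        else:
            beta3[int_idx] = rng.normal(0.0, config.effect_size_sd, size=n_int)

    meanlog_a, sdlog_a = config.dispersion_lognormal_params
    alpha = rng.lognormal(meanlog_a, sdlog_a, size=n_genes)
    if (alpha <= 0).any():
        raise ConfigurationError("nonpositive dispersion drawn")
    b = rng.normal(0.0, config.sigma_b, size=(n_genes, n_pat)) if config.sigma_b > 0 \
        else np.zeros((n_genes, n_pat))

    arm_s = arm[sample_patient].astype(float)
    eta = (offsets[None, :]
           + beta0[:, None]
           + beta1[:, None] * sample_time[None, :]
           + beta2[:, None] * arm_s[None, :]
           + beta3[:, None] * (sample_time * arm_s)[None, :]
           + b[:, sample_patient])
    mu = np.exp(eta)
    r = 1.0 / alpha[:, None]
    # NB as gamma-Poisson; near-zero dispersion degenerates to Poisson
    tiny = alpha < 1e-12
    lam = np.where(tiny[:, None], mu, rng.gamma(np.broadcast_to(r, mu.shape),
                                                mu / np.broadcast_to(r, mu.shape)))
    counts = rng.poisson(lam)

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "patient_id": [patients[p] for p in sample_patient],
            "time": sample_time.astype(int),
            "visit_week": [config.timepoints[int(t)] for t in sample_time],
            "group": arm_s.astype(int),
            "medication": [config.medications[int(a)] for a in arm_s],
            "library_size": lib,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    data = LongitudinalCountData(counts_df, meta)
    truth = GroundTruth(
        beta=pd.DataFrame(
            {"beta0": beta0, "beta1": beta1, "beta2": beta2, "beta3": beta3},
            index=gene_ids),
        alpha=pd.Series(alpha, index=gene_ids, name="alpha"),
        random_intercepts=pd.DataFrame(b, index=gene_ids, columns=patients),
        library_sizes=pd.Series(lib, index=sample_ids, name="library_size"),
        arm=pd.Series(arm, index=patients, name="arm"),
        interaction_genes=pd.Index([gene_ids[i] for i in sorted(int_idx)]),
    )
    return data, truth


_SCORE_RANGES = {"cd20": 4, "cd3": 4, "cd138": 4, "cd68l": 4, "cd68sl": 4,
                 "cd79a": 4, "krenn": 9}


def generate_histology(config: SimulationConfig,
                       latent_correlation: float = 0.7) -> pd.DataFrame:
    """Semiquantitative biopsy scores driven by a per-patient latent
    inflammation factor z ~ N(0,1): each score thresholds
    rho*z + sqrt(1-rho^2)*eps into equal-probability ordinal bins
    (0-4; Krenn 0-9)."""
    rho = float(latent_correlation)
    if not (0.0 <= rho <= 1.0):
        raise ConfigurationError("latent_correlation must lie in [0, 1]")
    rng = config.rng(_STREAM_HISTOLOGY)
    n = config.n_patients
    z = rng.normal(size=n)
    from scipy.stats import norm
    out = {}
    for name, hi in _SCORE_RANGES.items():
        eps = rng.normal(size=n)
        latent = rho * z + np.sqrt(1.0 - rho**2) * eps
        n_bins = hi + 1
        # equal-probability bins of the standard normal
        cuts = norm.ppf(np.arange(1, n_bins) / n_bins)
        out[name] = np.searchsorted(cuts, latent, side="right")
    df = pd.DataFrame(out, index=pd.Index([f"P{i:04d}" for i in range(n)],
                                          name="patient_id"))
    df["latent_z"] = z
    return df


def generate_cdai_course(
    config: SimulationConfig,
    stratum_effects: Optional[Dict[str, float]] = None,
    strata: Optional[Sequence[str]] = None,
    baseline_range: Tuple[float, float] = (20.0, 50.0),
    sigma_patient: float = 3.0,
    sigma_noise: float = 2.0,
) -> pd.DataFrame:
    """CDAI trajectories over months 0..4.

    CDAI_it = clamp(baseline_i + slope(arm_i, stratum_i) * t + u_i + eps_it,
    0, 76), where ``stratum_effects`` maps a stratum to the extra per-month
    slope applied in arm 1 (arm x time interaction); arm 0 follows a common
    mild improvement.  Components (TJC 0-28, SJC 0-28, globals 0-10) are
    back-filled so they sum exactly to the stored total.
    """
    rng = config.rng(_STREAM_CDAI)
    n = config.n_patients
    stratum_effects = stratum_effects or {}
    if strata is None:
        names = sorted(stratum_effects) or ["all"]
        strata = [names[i % len(names)] for i in range(n)]
    strata = list(strata)
    if len(strata) != n:
        raise ConfigurationError("strata must have one entry per patient")
    arm = np.tile([0, 1], (n + 1) // 2)[:n]
    baseline = rng.uniform(*baseline_range, size=n)
    u = rng.normal(0.0, sigma_patient, size=n) if sigma_patient > 0 else np.zeros(n)
    base_slope = -1.0  # mild common improvement per month in both arms
    rows = []
    for i in range(n):
        extra = stratum_effects.get(strata[i], 0.0) if arm[i] == 1 else 0.0
        slope = base_slope + extra
        for month in range(5):
            eps = rng.normal(0.0, sigma_noise) if sigma_noise > 0 else 0.0
            total = float(np.clip(baseline[i] + slope * month + u[i] + eps, 0.0, 76.0))
            tjc, sjc, ptga, ehga = _components_from_total(total)
            rows.append({
                "patient_id": f"P{i:04d}", "visit_month": month,
                "medication": config.medications[arm[i]], "arm": int(arm[i]),
                "stratum": strata[i], "tjc": tjc, "sjc": sjc,
                "ptga": ptga, "ehga": ehga, "cdai": total,
            })
    return pd.DataFrame(rows)


def _components_from_total(total: float) -> Tuple[int, int, float, float]:
    """Split a CDAI total into (TJC, SJC, patient global, evaluator global)
    with integer joint counts, globals in [0, 10], and an exact sum."""
    tjc = int(np.clip(np.floor(total * 28.0 / 76.0), 0, 28))
    sjc = int(np.clip(np.floor(total * 28.0 / 76.0), 0, 28))
    rem = total - tjc - sjc
    # rem <= 20 + 2 from flooring; push any excess above the global caps back
    while rem > 20.0 and (tjc < 28 or sjc < 28):
        if tjc < 28:
            tjc += 1
        elif sjc < 28:
            sjc += 1
        rem = total - tjc - sjc
    ptga = min(10.0, rem / 2.0)
    ehga = rem - ptga
    return tjc, sjc, float(ptga), float(ehga)
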