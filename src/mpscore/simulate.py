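"""Synthetic expression + survival cohorts with known planted structure.

The generator emulates the shape of a bulk tumor expression study with
matched clinical follow-up: a gene-by-sample log2-scale matrix over tumor and
normal samples, differential expression between the groups, a subset of genes
whose expression state carries prognostic information, right-censored overall
survival from a Weibull proportional-hazards model, and dichotomized clinical
covariates. Every planted quantity is returned as ground truth so each
downstream stage has a parameter-recovery test.

Prognostic structure comes from latent co-expressed risk programs: each tumor
sample carries n_risk_programs independent latent risk states L_k (Bernoulli
1/2), every planted prognostic gene is a bimodal reporter of one program with
widely separated modes (so a median split on the gene recovers its program's
state), and the hazard carries planted_log_hr x L_k once per program. With
the default single program the marginal median-split hazard ratio of each
planted gene equals exp(planted_log_hr) exactly - no attenuation from other
omitted effects - which is what the parameter-recovery tests assert. With
several programs the summed risk is graded (useful for end-to-end ranking
checks) but each gene's marginal hazard ratio is attenuated below the
conditional one by the usual Cox non-collapsibility. Null genes are
independent Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CLINICAL_LEVELS,
    DAYS_PER_YEAR,
    ClinicalTable,
    ExpressionMatrix,
    MpsValidationError,
)

#: prevalence of the non-reference level of each clinical covariate
DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "age_group": 0.50,
    "gender": 0.65,
    "grade_group": 0.54,
    "stage_group": 0.39,
    "t_group": 0.36,
    "n_status": 0.06,
    "m_status": 0.16,
    "hemoglobin": 0.45,
    "platelet": 0.10,
    "calcium": 0.35,
}

#: fraction of samples whose level is masked to the missing-information code
DEFAULT_UNKNOWN_RATES: dict[str, float] = {
    "n_status": 0.30,
    "m_status": 0.05,
    "hemoglobin": 0.05,
    "platelet": 0.05,
    "calcium": 0.05,
}

#: separation between the two expression modes of a planted prognostic gene,
#: in units of noise_sd; 6 sd keeps median-split misclassification ~0.1%
RISK_GENE_SEPARATION_SD = 6.0


@dataclass
class SimulationConfig:
    """Cohort-generator settings; defaults mirror a TCGA-ccRCC-sized study."""

    n_tumor: int = 531
    n_normal: int = 72
    n_genes: int = 1000
    n_prognostic: int = 30
    n_de: int = 150
    planted_log_hr: float = math.log(2.0)
    planted_log2fc: float = 2.5
    baseline_scale: float = 2400.0  # Weibull scale, days
    baseline_shape: float = 1.1
    censor_rate: float = 0.68
    noise_sd: float = 1.0
    seed: int = 0
    n_risk_programs: int = 1
    de_overlaps_prognostic: bool = True
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    covariate_betas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes", "n_prognostic", "n_de"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise MpsValidationError(f"{name} must be a nonnegative integer (got {v!r})")
        if self.n_prognostic > self.n_genes:
            raise MpsValidationError("n_prognostic must be <= n_genes")
        if self.n_de > self.n_genes:
            raise MpsValidationError("n_de must be <= n_genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise MpsValidationError("censor_rate must be in [0, 1)")
        if not self.noise_sd > 0:
            raise MpsValidationError("noise_sd must be positive")
        if not (self.baseline_scale > 0 and self.baseline_shape > 0):
            raise MpsValidationError("baseline_scale and baseline_shape must be positive")
        if self.n_risk_programs < 1:
            raise MpsValidationError("n_risk_programs must be >= 1")
        for k in self.covariate_betas:
            if k not in CLINICAL_LEVELS:
                raise MpsValidationError(f"covariate_betas: unknown covariate {k!r}")


@dataclass
class GroundTruth:
    prognostic_genes: list[str]
    de_genes: list[str]
    true_log_hr: dict[str, float]
    true_log2fc: dict[str, float]
    true_covariate_betas: dict[str, float]
    risk_group: dict[str, int]  # number of high-risk latent programs per tumor sample

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _censoring_rate_for(times: np.ndarray, target: float) -> float:
    """Exponential censoring rate r with mean_i P(C < t_i) = target."""
    if target <= 0:
        return 0.0

    def frac(log_r: float) -> float:
        return float(np.mean(1.0 - np.exp(-np.exp(log_r) * times))) - target

    lo, hi = -30.0, 10.0
    # widen if needed (times in days can be large)
    while frac(lo) > 0 and lo > -60:
        lo -= 10
    while frac(hi) < 0 and hi < 60:
        hi += 10
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Generate (expression, clinical, ground truth); bit-identical per seed."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    tumor_ids = [f"T{i:05d}" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"N{i:05d}" for i in range(1, config.n_normal + 1)]
    n_t, n_n, g = config.n_tumor, config.n_normal, config.n_genes

    prognostic = genes[: config.n_prognostic]
    if config.de_overlaps_prognostic:
        de = genes[: config.n_de]
    else:
        if config.n_prognostic + config.n_de > g:
            raise MpsValidationError("n_prognostic + n_de exceed n_genes with no overlap")
        de = genes[config.n_prognostic : config.n_prognostic + config.n_de]

    values = rng.normal(0.0, config.noise_sd, size=(g, n_t + n_n))
    de_idx = [genes.index(s) for s in de]
    values[de_idx, :n_t] += config.planted_log2fc

    k = min(config.n_risk_programs, max(config.n_prognostic, 1))
    if config.n_prognostic:
        latent = rng.integers(0, 2, size=(k, n_t))
        sep = RISK_GENE_SEPARATION_SD * config.noise_sd
        program = np.arange(config.n_prognostic) % k  # round-robin gene -> program
        values[: config.n_prognostic, :n_t] += (latent[program] - 0.5) * sep
        risk_load = latent.sum(axis=0)
    else:
        latent = np.zeros((k, n_t), dtype=int)
        risk_load = np.zeros(n_t, dtype=int)

    # clinical covariates: independent Bernoullis, then mask some to unknown
    cov_cols: dict[str, np.ndarray] = {}
    cov_binary: dict[str, np.ndarray] = {}
    for var, levels in CLINICAL_LEVELS.items():
        prev = float(config.covariate_prevalences.get(var, 0.5))
        b = (rng.random(n_t) < prev).astype(int)
        cov_binary[var] = b
        lab = np.where(b == 1, levels[1], levels[0]).astype(object)
        unk = DEFAULT_UNKNOWN_RATES.get(var, 0.0)
        if unk > 0 and len(levels) > 2:
            mask = rng.random(n_t) < unk
            lab[mask] = levels[2]
        cov_cols[var] = lab

    betas = {name: float(v) for name, v in config.covariate_betas.items()}
    # center the risk load so a median-risk patient follows the baseline Weibull;
    # shifting the linear predictor by a constant leaves every hazard ratio intact
    center = k / 2.0 if config.n_prognostic else 0.0
    lp = config.planted_log_hr * (risk_load.astype(float) - center)
    for var, beta in betas.items():
        lp = lp + beta * cov_binary[var]

    if n_t:
        u = rng.random(n_t)
        t_event = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)
        if config.censor_rate > 0:
            rate = _censoring_rate_for(t_event, config.censor_rate)
            c = rng.exponential(1.0 / rate, size=n_t)
            os_time = np.minimum(t_event, c)
            os_event = (t_event <= c).astype(int)
        else:
            os_time, os_event = t_event, np.ones(n_t, dtype=int)
    else:
        os_time = np.array([], dtype=float)
        os_event = np.array([], dtype=int)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=tumor_ids + normal_ids),
        pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=tumor_ids + normal_ids),
    )
    clin_df = pd.DataFrame({"os_time": os_time, "os_event": os_event, **cov_cols},
                           index=pd.Index(tumor_ids, name="sample_id"))
    clinical = ClinicalTable(clin_df)
    truth = GroundTruth(
        prognostic_genes=list(prognostic),
        de_genes=list(de),
        true_log_hr={s: config.planted_log_hr for s in prognostic},
        true_log2fc={s: config.planted_log2fc for s in de},
        true_covariate_betas=betas,
        risk_group={sid: int(z) for sid, z in zip(tumor_ids, risk_load)},
    )
    return expr, clinical, truth


def event_status_at(clinical: ClinicalTable, horizon: float) -> pd.Series:
    """Vital status at a horizon (days): "alive", "dead" or "unknown".

    dead: event observed at or before the horizon; alive: follow-up (with or
    without a later event) extends past the horizon; unknown: censored before
    the horizon.
    """
    if not horizon > 0:
        raise MpsValidationError("horizon must be positive")
    t = clinical.os_time
    if (t < 0).any():
        raise MpsValidationError("negative survival times")
    e = clinical.os_event
    status = pd.Series("unknown", index=t.index, dtype=object)
    status[t > horizon] = "alive"
    status[(e == 1) & (t <= horizon)] = "dead"
    return status


def three_year_labels(clinical: ClinicalTable, years: float = 3.0) -> pd.Series:
    """Binary labels (alive=0, deceased=1) at `years`; unknown samples dropped."""
    status = event_status_at(clinical, years * DAYS_PER_YEAR)
    known = status[status != "unknown"]
    return (known == "dead").astype(int)
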