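"""Stage 1 of panel construction: prognosis-associated and DE genes.

Every gene is screened twice. The survival screen splits tumor samples at the
gene's median expression (ties go to the low group), fits a Cox model on the
binary high-vs-low indicator for the hazard ratio and Wald CI, and tests the
two groups with a log-rank test. Differential expression between tumor and
normal samples uses an empirical-Bayes moderated t-statistic with
Benjamini-Hochberg adjustment; genes pass at adj_p < alpha and |log2FC|
above the fold-change cutoff. The candidate list is the intersection of both
screens, ordered by survival p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from ._coxfast import cox_binary, logrank_two_group
from .io import ClinicalTable, ExpressionMatrix, MpsValidationError, align_samples

DEFAULT_DE_ALPHA = 0.05
DEFAULT_DE_LOG2FC = 2.0  # strict |log2FC| > 2


@dataclass(frozen=True)
class GeneSurvivalResult:
    symbol: str
    median_cutoff: float
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    wald_p: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise MpsValidationError(f"{self.symbol}: CI does not bracket HR")


def _split_indicator(values: np.ndarray) -> tuple[np.ndarray, float]:
    cutoff = float(np.median(values))
    return (values > cutoff).astype(int), cutoff


def median_split_survival(
    expr: ExpressionMatrix, clinical: ClinicalTable, gene: str
) -> GeneSurvivalResult:
    """Median-split hazard ratio and log-rank p for one gene (tumor samples)."""
    if gene not in expr.values.index:
        raise KeyError(gene)
    expr, clinical = align_samples(expr, clinical, mode="strict")
    vals = expr.values.loc[gene, expr.tumor_ids()].to_numpy(dtype=float)
    x, cutoff = _split_indicator(vals)
    if x.sum() == 0 or x.sum() == len(x):
        raise MpsValidationError(f"{gene}: constant expression, one median-split group is empty")
    if min(x.sum(), len(x) - x.sum()) < 2:
        raise MpsValidationError(f"{gene}: fewer than 2 samples in a median-split group")
    time = clinical.os_time.to_numpy()
    event = clinical.os_event.to_numpy()
    fit = cox_binary(time, event, x)
    _, lr_p = logrank_two_group(time, event, x)
    return GeneSurvivalResult(
        symbol=gene,
        median_cutoff=cutoff,
        hr=fit.hr,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        logrank_p=lr_p,
        wald_p=fit.wald_p,
    )


@dataclass
class ScreenResult:
    """Full per-gene survival-screen table plus the screening threshold."""

    table: pd.DataFrame  # index symbol; columns median_cutoff, hr, ci_*, logrank_p, wald_p, flag
    alpha: float

    @property
    def passing(self) -> list[str]:
        ok = self.table[(self.table["flag"] == "ok") & (self.table["logrank_p"] < self.alpha)]
        return list(ok.sort_values("logrank_p").index)

    def result_for(self, gene: str) -> GeneSurvivalResult:
        r = self.table.loc[gene]
        if r["flag"] != "ok":
            raise MpsValidationError(f"{gene}: not scoreable ({r['flag']})")
        return GeneSurvivalResult(
            symbol=gene, median_cutoff=float(r["median_cutoff"]), hr=float(r["hr"]),
            ci_low=float(r["ci_low"]), ci_high=float(r["ci_high"]),
            logrank_p=float(r["logrank_p"]), wald_p=float(r["wald_p"]),
        )


def screen_survival(
    expr: ExpressionMatrix, clinical: ClinicalTable, alpha: float = 0.05
) -> ScreenResult:
    """Median-split survival screen over every gene; keep logrank_p < alpha.

    Genes whose median split leaves a group with <2 samples are flagged
    ("constant") and never pass. The full table is retained for reporting.
    """
    if not 0.0 <= alpha <= 1.0:
        raise MpsValidationError("alpha must be in [0, 1]")
    expr, clinical = align_samples(expr, clinical, mode="strict")
    tumor = expr.tumor_ids()
    if clinical.os_event.sum() == 0:
        raise MpsValidationError("no events in cohort; survival screen undefined")
    time = clinical.os_time.to_numpy()
    event = clinical.os_event.to_numpy()
    mat = expr.values[tumor].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(expr.gene_symbols):
        x, cutoff = _split_indicator(mat[i])
        n1 = int(x.sum())
        if min(n1, len(x) - n1) < 2:
            rows.append((gene, cutoff, np.nan, np.nan, np.nan, np.nan, np.nan, "constant"))
            continue
        fit = cox_binary(time, event, x)
        _, lr_p = logrank_two_group(time, event, x)
        flag = "ok" if fit.converged else "separation"
        rows.append((gene, cutoff, fit.hr, fit.ci_low, fit.ci_high, lr_p, fit.wald_p, flag))
    table = pd.DataFrame(
        rows,
        columns=["symbol", "median_cutoff", "hr", "ci_low", "ci_high", "logrank_p", "wald_p", "flag"],
    ).set_index("symbol")
    return ScreenResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# moderated-t differential expression


def _fit_log_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene variances.

    Method of moments on z = log(s2): under the scaled inverse chi-square
    hierarchy, Var(z) = trigamma(df/2) + trigamma(d0/2) and
    E(z) = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2).
    """
    z = np.log(s2)
    var_z = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    excess = var_z - float(special.polygamma(1, df / 2.0))
    if excess <= 1e-8:
        d0 = np.inf
    else:
        # invert trigamma(d0/2) = excess
        f = lambda d: float(special.polygamma(1, d / 2.0)) - excess
        lo, hi = 1e-6, 1e8
        d0 = float(brentq(f, lo, hi)) if f(lo) > 0 > f(hi) else np.inf
    mean_z = float(np.mean(z))
    adj = float(special.digamma(df / 2.0)) - np.log(df / 2.0)
    if np.isfinite(d0):
        adj -= float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0)
    s0_2 = float(np.exp(mean_z - adj))
    return d0, s0_2


def differential_expression(
    expr: ExpressionMatrix,
    alpha: float = DEFAULT_DE_ALPHA,
    log2fc_cutoff: float = DEFAULT_DE_LOG2FC,
) -> pd.DataFrame:
    """Tumor-vs-normal moderated t-test per gene, BH-adjusted.

    log2fc = mean(tumor) - mean(normal) on the log2 input scale. Gene
    variances are shrunk toward a pooled prior estimated across genes
    (empirical Bayes); the moderated t has df = residual df + prior df.
    Returns a DataFrame indexed by symbol with columns log2fc, t_stat, p,
    adj_p and passes (adj_p < alpha AND |log2fc| > log2fc_cutoff).
    """
    tumor, normal = expr.tumor_ids(), expr.normal_ids()
    n1, n2 = len(tumor), len(normal)
    if n1 < 2 or n2 < 2:
        raise MpsValidationError("need at least 2 tumor and 2 normal samples")
    t_mat = expr.values[tumor].to_numpy(dtype=float)
    n_mat = expr.values[normal].to_numpy(dtype=float)
    fc = t_mat.mean(axis=1) - n_mat.mean(axis=1)
    ss = t_mat.var(axis=1, ddof=1) * (n1 - 1) + n_mat.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    s2 = ss / df
    if np.all(t_mat.var(axis=1, ddof=1) == 0) or np.all(n_mat.var(axis=1, ddof=1) == 0):
        raise MpsValidationError("a sample group has zero variance across all genes")
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise MpsValidationError("all genes have zero pooled variance")
    d0, s0_2 = _fit_log_variance_prior(positive, df)
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        s2_post = np.full_like(s2, s0_2)
        df_total = 1e6
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_stat = np.where(se > 0, fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=min(df_total, 1e6))
    adj_p = multipletests(p, method="fdr_bh")[1]
    adj_p = np.maximum(adj_p, p)  # BH never reports below the raw p
    out = pd.DataFrame(
        {
            "log2fc": fc,
            "t_stat": t_stat,
            "p": p,
            "adj_p": adj_p,
            "passes": (adj_p < alpha) & (np.abs(fc) > log2fc_cutoff),
        },
        index=pd.Index(expr.gene_symbols, name="symbol"),
    )
    return out


def intersect_prognostic_de(
    survival_hits: list[str] | ScreenResult, de_hits: list[str] | pd.DataFrame
) -> list[str]:
    """Genes passing both screens, ordered by survival p ascending."""
    if isinstance(survival_hits, ScreenResult):
        survival_hits = survival_hits.passing
    if isinstance(de_hits, pd.DataFrame):
        de_hits = list(de_hits.index[de_hits["passes"]])
    de_set = set(de_hits)
    return [g for g in survival_hits if g in de_set]
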