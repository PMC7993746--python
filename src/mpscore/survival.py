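"""Survival evaluation: KM/log-rank, Cox models, C-index, nomogram, calibration.

Model fitting is delegated to lifelines (Cox PH with Efron tie handling,
Kaplan-Meier, k-group log-rank). On top of that this module implements the
evaluation workflow: the univariate -> multivariate carry-forward rule
(univariate p < 0.05 enters the multivariate model), a points-based nomogram
derived from a multivariate fit with Breslow baseline survival at fixed
horizons, and binned calibration curves with optional bootstrap optimism
adjustment. Covariates enter as the fixed dichotomies defined in
`mpscore.io.CLINICAL_LEVELS`; missing-information levels are deleted listwise
per model with the used sample count reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

from .io import DAYS_PER_YEAR, ClinicalTable, MpsValidationError, encode_covariates

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS_YEARS = (3.0, 5.0)


@dataclass
class KmCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray  # product-limit estimate at each time
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value of the survival estimate at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_logrank(
    clinical: ClinicalTable, group_labels: pd.Series
) -> tuple[list[KmCurve], float, float]:
    """Kaplan-Meier curve per group plus the k-group log-rank test."""
    groups = group_labels.reindex(clinical.sample_ids)
    if groups.isna().any():
        raise MpsValidationError("group label missing for some samples")
    uniq = groups.unique()
    if len(uniq) < 2:
        raise MpsValidationError("log-rank comparison requires at least 2 groups")
    if clinical.os_event.sum() == 0:
        raise MpsValidationError("no events observed")
    curves = []
    for g in sorted(map(str, uniq)):
        sel = groups.astype(str) == g
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.os_time[sel], clinical.os_event[sel], label=g)
        tbl = kmf.event_table
        curves.append(
            KmCurve(
                label=g,
                times=kmf.survival_function_.index.to_numpy(dtype=float),
                survival=kmf.survival_function_[g].to_numpy(dtype=float),
                at_risk=tbl["at_risk"].to_numpy(dtype=float),
            )
        )
    res = multivariate_logrank_test(clinical.os_time, groups, clinical.os_event)
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted proportional-hazards model plus its design data."""

    summary: pd.DataFrame  # index variable; beta, se, hr, ci_low, ci_high, p
    model_type: str  # "univariate" | "multivariate"
    n_used: int
    model: CoxPHFitter = field(repr=False)
    data: pd.DataFrame = field(repr=False)  # complete-case design incl. os_time/os_event

    @property
    def variables(self) -> list[str]:
        return list(self.summary.index)

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        beta = self.summary["beta"]
        return X[self.variables].astype(float) @ beta

    def baseline_survival(self, times: np.ndarray) -> np.ndarray:
        """S0(t) for the all-zero covariate vector (Breslow estimator)."""
        zero = pd.DataFrame([dict.fromkeys(self.variables, 0.0)])
        sf = self.model.predict_survival_function(zero, times=times)
        return sf.iloc[:, 0].to_numpy(dtype=float)

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> pd.DataFrame:
        return self.model.predict_survival_function(X[self.variables].astype(float), times=times)


def _design_frame(
    clinical: ClinicalTable,
    variables: list[str],
    extra_covariates: pd.DataFrame | None,
) -> tuple[pd.DataFrame, list[str]]:
    clin_vars = [v for v in variables if extra_covariates is None or v not in extra_covariates]
    enc = encode_covariates(clinical, clin_vars) if clin_vars else pd.DataFrame(index=clinical.table.index)
    if extra_covariates is not None:
        extra = extra_covariates.reindex(clinical.table.index)
        enc = enc.join(extra[[v for v in variables if v in extra_covariates.columns]])
    missing = [v for v in variables if v not in enc.columns]
    if missing:
        raise MpsValidationError(f"unknown covariate(s): {missing}")
    df = enc[variables].astype(float)
    df.insert(0, "os_time", clinical.os_time)
    df.insert(1, "os_event", clinical.os_event)
    complete = df.dropna()
    return complete, variables


def _fit_cox(df: pd.DataFrame, variables: list[str], model_type: str) -> CoxFit:
    if len(df) == 0:
        raise MpsValidationError("no complete cases for Cox fit")
    for v in variables:
        if df[v].nunique() < 2:
            raise MpsValidationError(f"covariate {v!r} is constant in complete cases")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="os_event")
    except ConvergenceError as exc:
        raise MpsValidationError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    ).loc[variables]
    if (summary["beta"].abs() > 15).any():
        bad = summary.index[summary["beta"].abs() > 15].tolist()
        raise MpsValidationError(f"likely separation: extreme coefficient(s) for {bad}")
    return CoxFit(summary=summary, model_type=model_type, n_used=len(df), model=cph, data=df)


def cox_univariate(
    clinical: ClinicalTable, variable: str, extra_covariates: pd.DataFrame | None = None
) -> CoxFit:
    df, variables = _design_frame(clinical, [variable], extra_covariates)
    return _fit_cox(df, variables, "univariate")


def cox_multivariate(
    clinical: ClinicalTable, variables: list[str], extra_covariates: pd.DataFrame | None = None
) -> CoxFit:
    if not variables:
        raise MpsValidationError("multivariate fit needs at least one variable")
    df, variables = _design_frame(clinical, list(variables), extra_covariates)
    return _fit_cox(df, variables, "multivariate")


def cox_screen(
    clinical: ClinicalTable,
    variables: list[str],
    extra_covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[dict[str, CoxFit], CoxFit | None]:
    """Univariate fits for every variable; carry p < alpha into a multivariate fit."""
    uni: dict[str, CoxFit] = {}
    for v in variables:
        try:
            uni[v] = cox_univariate(clinical, v, extra_covariates)
        except MpsValidationError as exc:
            logger.warning("univariate fit skipped for %s: %s", v, exc)
    carried = [v for v, f in uni.items() if float(f.summary.loc[v, "p"]) < alpha]
    multi = cox_multivariate(clinical, carried, extra_covariates) if carried else None
    return uni, multi


def concordance_index(
    scores: pd.Series, clinical: ClinicalTable, higher_is: str = "risk"
) -> float:
    """Harrell's C over comparable pairs; prediction ties count 1/2.

    higher_is declares the orientation of the score: "risk" (higher score =
    earlier failure expected) or "survival".
    """
    if higher_is not in ("risk", "survival"):
        raise MpsValidationError("higher_is must be 'risk' or 'survival'")
    s = pd.Series(scores).reindex(clinical.sample_ids)
    if s.isna().any():
        raise MpsValidationError("score missing for some samples")
    if clinical.os_event.sum() == 0:
        raise MpsValidationError("no comparable pairs: no events observed")
    pred = -s if higher_is == "risk" else s  # lifelines: higher = longer survival
    c = _lifelines_cindex(clinical.os_time, pred, clinical.os_event)
    if c >= 0.70:
        logger.info("C-index %.3f >= 0.70 (conventionally 'good fit')", c)
    return float(c)


# ---------------------------------------------------------------------------
# nomogram


@dataclass
class Nomogram:
    """Points representation of a multivariate Cox fit.

    Each variable's contribution beta_i * x_i is mapped to 0..points_i with
    the largest single-variable span normalized to 100 points. Total points
    map affinely back to the linear predictor (lp = unit * points + offset),
    and survival at the stored horizons is S0(t)^exp(lp) with the Breslow
    baseline S0 taken at the all-zero covariate vector.
    """

    variables: list[str]
    betas: pd.Series
    contribution_min: pd.Series  # min of beta_i * x_i over the fitting data
    unit: float  # lp per point
    horizons: tuple[float, ...]  # days
    baseline_at_horizons: np.ndarray  # S0 at each horizon
    c_index: float
    fit: CoxFit = field(repr=False)

    @property
    def offset(self) -> float:
        return float(self.contribution_min.sum())

    def points(self, X: pd.DataFrame) -> pd.DataFrame:
        contrib = X[self.variables].astype(float) * self.betas
        return (contrib - self.contribution_min) / self.unit

    def total_points(self, X: pd.DataFrame) -> pd.Series:
        return self.points(X).sum(axis=1)

    def linear_predictor_from_points(self, total_points) -> np.ndarray:
        return np.asarray(total_points, dtype=float) * self.unit + self.offset

    def predict_survival_from_points(self, total_points, horizon: float) -> np.ndarray:
        try:
            h = self.horizons.index(horizon)
        except ValueError as exc:
            raise MpsValidationError(f"horizon {horizon} not tabulated") from exc
        lp = self.linear_predictor_from_points(total_points)
        return self.baseline_at_horizons[h] ** np.exp(lp)

    def predict_survival(self, X: pd.DataFrame, horizon: float) -> np.ndarray:
        return self.predict_survival_from_points(self.total_points(X), horizon)


def build_nomogram(
    fit: CoxFit, horizons_years: tuple[float, ...] = DEFAULT_HORIZONS_YEARS
) -> Nomogram:
    """Points-based nomogram from a multivariate Cox fit (3-/5-year OS default)."""
    if fit.model_type != "multivariate":
        raise MpsValidationError("nomogram requires a multivariate Cox fit")
    betas = fit.summary["beta"]
    if (betas == 0).all():
        raise MpsValidationError("all coefficients are zero; nomogram undefined")
    X = fit.data[fit.variables].astype(float)
    contrib = X * betas
    span = contrib.max() - contrib.min()
    unit = float(span.max()) / 100.0
    horizons = tuple(float(h) * DAYS_PER_YEAR for h in horizons_years)
    last = float(fit.data["os_time"].max())
    if any(h > last for h in horizons):
        logger.warning("a nomogram horizon exceeds the last observed time %.0f days", last)
    s0 = fit.baseline_survival(np.asarray(horizons))
    lp = fit.linear_predictor(X)
    c = float(_lifelines_cindex(fit.data["os_time"], -lp, fit.data["os_event"]))
    return Nomogram(
        variables=fit.variables,
        betas=betas,
        contribution_min=contrib.min(),
        unit=unit,
        horizons=horizons,
        baseline_at_horizons=s0,
        c_index=c,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# calibration


def _binned_curve(pred: pd.Series, data: pd.DataFrame, horizon: float, bin_edges: np.ndarray):
    """Per-bin (predicted mean, observed KM at horizon, n, flagged)."""
    idx = np.clip(np.searchsorted(bin_edges, pred.to_numpy(), side="right") - 1, 0, len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            rows.append((np.nan, np.nan, 0, True))
            continue
        sub = data.loc[pred.index[sel]]
        at_risk_at_h = int((sub["os_time"] >= horizon).sum())
        events = int(sub["os_event"].sum())
        flagged = events == 0 and at_risk_at_h == 0
        kmf = KaplanMeierFitter().fit(sub["os_time"], sub["os_event"])
        rows.append((float(pred[sel].mean()), float(kmf.predict(horizon)), n, flagged))
    return pd.DataFrame(rows, columns=["predicted", "observed", "n", "flagged"])


def calibration(
    nomogram: Nomogram,
    horizon_years: float,
    n_bins: int = 3,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned predicted vs observed survival at a horizon.

    Samples are binned by predicted survival (default tertiles); observed is
    the within-bin KM estimate at the horizon. With n_boot > 0, the model is
    refit on bootstrap resamples to estimate per-bin optimism (Harrell's
    apparent-minus-test scheme) and an optimism-adjusted observed column is
    added. n_boot = 0 returns the apparent curve only.
    """
    horizon = float(horizon_years) * DAYS_PER_YEAR
    fit = nomogram.fit
    data = fit.data
    if horizon > float(data["os_time"].max()):
        raise MpsValidationError("horizon beyond the last observed time")
    X = data[fit.variables]
    pred = pd.Series(_predict_at(fit, X, horizon), index=data.index)
    edges = np.quantile(pred, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    apparent = _binned_curve(pred, data, horizon, edges)
    apparent["error"] = apparent["observed"] - apparent["predicted"]
    if n_boot <= 0:
        return apparent
    rng = np.random.default_rng(seed)
    optimism = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for _ in range(n_boot):
        bidx = rng.integers(0, len(data), size=len(data))
        boot = data.iloc[bidx].reset_index(drop=True)
        try:
            bfit = _fit_cox(boot, fit.variables, "multivariate")
        except MpsValidationError:
            continue
        bpred = pd.Series(_predict_at(bfit, boot[fit.variables], horizon), index=boot.index)
        bedges = np.quantile(bpred, np.linspace(0, 1, n_bins + 1))
        bedges[0], bedges[-1] = -np.inf, np.inf
        app_b = _binned_curve(bpred, boot, horizon, bedges)
        tpred = pd.Series(_predict_at(bfit, X, horizon), index=data.index)
        test_b = _binned_curve(tpred, data, horizon, bedges)
        err_app = (app_b["observed"] - app_b["predicted"]).to_numpy()
        err_test = (test_b["observed"] - test_b["predicted"]).to_numpy()
        ok = np.isfinite(err_app) & np.isfinite(err_test)
        optimism[ok] += (err_app - err_test)[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        optimism = np.where(counts > 0, optimism / np.maximum(counts, 1), 0.0)
    out = apparent.copy()
    out["optimism"] = optimism
    out["observed_adjusted"] = out["observed"] - optimism
    out["n_boot"] = int(counts.max()) if len(counts) else 0
    return out


def _predict_at(fit: CoxFit, X: pd.DataFrame, horizon: float) -> np.ndarray:
    sf = fit.predict_survival(X, np.asarray([horizon]))
    return sf.iloc[0].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# optional plots


def plot_km(curves: list[KmCurve], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.step(c.times / DAYS_PER_YEAR, c.survival, where="post", label=c.label)
    ax.set_xlabel("years")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_calibration(curve: pd.DataFrame, path, horizon_label: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.plot(curve["predicted"], curve["observed"], "o-", label="apparent")
    if "observed_adjusted" in curve:
        ax.plot(curve["predicted"], curve["observed_adjusted"], "s-", label="optimism-adjusted")
    ax.set_xlabel(f"predicted survival {horizon_label}")
    ax.set_ylabel("observed (KM)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
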