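"""Fast single-covariate survival statistics for genome-wide screens.

A median-split screen fits one binary-covariate Cox model and one two-group
log-rank test per gene, for thousands of genes and many simulation
replicates. General-purpose fitters carry per-call overhead that dominates at
that scale, so the two statistics are implemented directly here: a Newton
solve of the Cox partial likelihood with Efron tie handling, and the standard
hypergeometric-variance log-rank test. Both are cross-checked against
lifelines in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_MAX_ABS_BETA = 15.0


@dataclass(frozen=True)
class BinaryCoxResult:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    converged: bool


def _event_time_tables(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Per distinct event time: deaths (total / in group 1) and at-risk counts."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), x[order].astype(float)
    n = len(t)
    # at-risk counts just before index i: everyone with index >= first tie of t[i]
    # suffix sums give at-risk group-1 counts at each position
    suffix_g = np.concatenate([np.cumsum(g[::-1])[::-1], [0.0]])
    ut, first_idx = np.unique(t, return_index=True)
    # deaths per unique time
    d_tot = np.zeros(len(ut))
    d1 = np.zeros(len(ut))
    pos = np.searchsorted(ut, t)
    np.add.at(d_tot, pos, e.astype(float))
    np.add.at(d1, pos, e * g)
    keep = d_tot > 0
    r_tot = (n - first_idx).astype(float)[keep]
    r1 = suffix_g[first_idx][keep]
    return d_tot[keep], d1[keep], r_tot, r1


def cox_binary(time, event, x) -> BinaryCoxResult:
    """Cox PH fit of a single binary covariate, Efron ties, Wald inference.

    `x` is the group indicator (1 = high). Returns hazard(high)/hazard(low).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if event.sum() == 0:
        raise ValueError("no events observed; cannot fit Cox model")
    if len(np.unique(x)) < 2:
        raise ValueError("covariate is constant; one group is empty")
    d_tot, d1, r_tot, r1 = _event_time_tables(time, event, x)
    d0 = d_tot - d1
    r0 = r_tot - r1
    dmax = int(d_tot.max())
    j = np.arange(dmax)[None, :]  # Efron index within each tied set
    frac = np.where(j < d_tot[:, None], j / d_tot[:, None], np.nan)
    valid = j < d_tot[:, None]

    def derivatives(beta: float):
        eb = np.exp(beta)
        denom = (r0[:, None] - frac * d0[:, None]) + (r1[:, None] - frac * d1[:, None]) * eb
        a = r1[:, None] - frac * d1[:, None]  # group-1 at-risk mass per Efron term
        m = np.where(valid, a * eb / denom, 0.0)
        ll = float(beta * d1.sum() - np.log(np.where(valid, denom, 1.0)).sum())
        grad = float(d1.sum() - m.sum())
        hess = float(-(m - m * m).sum())
        return ll, grad, hess

    beta = 0.0
    converged = False
    ll, grad, hess = derivatives(beta)
    for _ in range(50):
        if hess >= -1e-12:
            break
        step = -grad / hess
        step = float(np.clip(step, -2.0, 2.0))
        new = beta + step
        ll_new, grad_new, hess_new = derivatives(new)
        # step halving on non-improvement
        halves = 0
        while ll_new < ll - 1e-12 and halves < 20:
            step /= 2.0
            new = beta + step
            ll_new, grad_new, hess_new = derivatives(new)
            halves += 1
        beta, ll, grad, hess = new, ll_new, grad_new, hess_new
        if abs(grad) < 1e-9 or abs(step) < 1e-10:
            converged = True
            break
        if abs(beta) > _MAX_ABS_BETA:  # monotone likelihood / separation
            break
    se = float(1.0 / np.sqrt(-hess)) if hess < 0 else np.inf
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # infinite CI under separation
        return BinaryCoxResult(
            beta=float(beta),
            se=se,
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - ci * se)),
            ci_high=float(np.exp(beta + ci * se)),
            wald_p=p,
            converged=converged and abs(beta) <= _MAX_ABS_BETA,
        )


def logrank_two_group(time, event, x) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    if len(np.unique(x)) < 2:
        raise ValueError("only one group present")
    d_tot, d1, r_tot, r1 = _event_time_tables(time, event, x)
    expected = d_tot * r1 / r_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_tot * (r1 / r_tot) * (1.0 - r1 / r_tot) * (r_tot - d_tot) / (r_tot - 1.0)
    var = np.where(r_tot > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((d1.sum() - expected.sum()) ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, df=1))
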