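"""Apply a gene panel to a cohort: per-sample mPS and prognostic strata.

mPS(sample) = sum over panel genes of Gene-Score x Gene-Weight, where the
Gene-Score is 1 when the sample's expression falls in the gene's favorable
state (above vs at-or-below the median cutoff, per the panel's
score_high/score_low flags). Strata are half-open bins [lower, upper); the
published scheme for the 21-gene ccRCC panel is low < 22 <= median < 30 <=
high, or a two-group split at 22 for small cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel, MpsValidationError

logger = logging.getLogger(__name__)

PUBLISHED_THRESHOLDS = (22.0, 30.0)
PUBLISHED_TWO_GROUP = (22.0,)


@dataclass(frozen=True)
class StratificationScheme:
    thresholds: tuple[float, ...] = PUBLISHED_THRESHOLDS
    labels: tuple[str, ...] = ("low", "median", "high")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise MpsValidationError("need exactly one more label than thresholds")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise MpsValidationError("thresholds must be strictly ascending")

    @classmethod
    def published_three_group(cls) -> "StratificationScheme":
        return cls(PUBLISHED_THRESHOLDS, ("low", "median", "high"))

    @classmethod
    def published_two_group(cls) -> "StratificationScheme":
        return cls(PUBLISHED_TWO_GROUP, ("low", "high"))

    @classmethod
    def from_quantiles(
        cls, scores, quantiles=(1 / 3, 2 / 3), labels=("low", "median", "high")
    ) -> "StratificationScheme":
        """Data-driven thresholds at the given score quantiles.

        Used for freshly trained panels, whose weight scale is arbitrary and
        for which fixed published cutoffs are meaningless.
        """
        scores = np.asarray(scores, dtype=float)
        thresholds = tuple(float(np.quantile(scores, q)) for q in quantiles)
        return cls(thresholds, tuple(labels))

    def assign(self, mps) -> pd.Series | str:
        """Stratum label(s): bin k iff thresholds[k-1] <= mps < thresholds[k]."""
        arr = np.atleast_1d(np.asarray(mps, dtype=float))
        idx = np.searchsorted(np.asarray(self.thresholds), arr, side="right")
        lab = np.asarray(self.labels, dtype=object)[idx]
        if np.isscalar(mps) or getattr(mps, "ndim", 1) == 0:
            return str(lab[0])
        index = mps.index if isinstance(mps, pd.Series) else None
        return pd.Series(lab, index=index)


@dataclass(frozen=True)
class MedianReference:
    """Per-gene median cutoffs carried over from a reference cohort."""

    cutoffs: pd.Series  # index = panel gene symbols
    source: str = ""


def compute_mps(score_matrix: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """mPS per sample from a binary genes x samples Gene-Score matrix."""
    missing = [g for g in panel.symbols if g not in score_matrix.index]
    if missing:
        raise MpsValidationError(f"score matrix missing panel gene(s): {missing}")
    sub = score_matrix.loc[panel.symbols]
    vals = sub.to_numpy(dtype=float)
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise MpsValidationError("score matrix must be binary")
    mps = panel.weights.to_numpy() @ vals
    return pd.DataFrame({"mps": mps}, index=pd.Index(sub.columns, name="sample_id"))


def stratify(results: pd.DataFrame, scheme: StratificationScheme | None = None) -> pd.DataFrame:
    """Add a stratum column to an mPS results frame."""
    scheme = scheme or StratificationScheme.published_three_group()
    out = results.copy()
    out["stratum"] = scheme.assign(out["mps"])
    return out


def binarize_against_medians(
    expr: ExpressionMatrix, panel: GenePanel, medians: MedianReference | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Gene-Score matrix (panel genes x samples) for a cohort.

    medians=None computes cutoffs within the cohort (the default when scoring
    a new cohort); a MedianReference applies construction-cohort cutoffs.
    In permissive mode a missing panel gene is imputed as at-the-median (the
    low-expression state, so its score equals score_low); more than 20% of
    the panel missing is an error in any mode.
    """
    present = [g for g in panel.symbols if g in expr.values.index]
    missing = [g for g in panel.symbols if g not in expr.values.index]
    if missing:
        if len(missing) > 0.2 * len(panel):
            raise MpsValidationError(
                f">20% of panel genes absent from expression matrix: {missing}"
            )
        if strict:
            raise MpsValidationError(f"panel gene(s) absent from expression matrix: {missing}")
        logger.warning("imputing missing panel gene(s) as at-median: %s", missing)
    if expr.n_samples == 1 and medians is None:
        logger.warning(
            "single-sample cohort with per-cohort medians: every gene ties its own "
            "median and falls in the low-expression state"
        )
    scores = {}
    for entry in panel.entries:
        g = entry.symbol
        if g in present:
            if medians is not None:
                if g not in medians.cutoffs.index:
                    raise MpsValidationError(f"median reference missing cutoff for {g}")
                cutoff = float(medians.cutoffs.loc[g])
            else:
                cutoff = float(expr.values.loc[g].median())
            high = (expr.values.loc[g] > cutoff).astype(int)
        else:
            high = pd.Series(0, index=expr.values.columns)  # imputed at-median -> low state
        scores[g] = high if entry.score_high == 1 else 1 - high
    out = pd.DataFrame(scores).T.loc[panel.symbols]
    out.index.name = "symbol"
    return out


def score_cohort(
    expr: ExpressionMatrix,
    panel: GenePanel,
    medians: MedianReference | None = None,
    scheme: StratificationScheme | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Binarize, score and stratify a cohort; returns sample_id -> mps, stratum."""
    scores = binarize_against_medians(expr, panel, medians=medians, strict=strict)
    return stratify(compute_mps(scores, panel), scheme)
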