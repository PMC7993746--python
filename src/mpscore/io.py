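"""Core data containers and TSV/JSON readers and writers.

All tabular files are UTF-8, tab-separated, '.' decimal. Expression matrices
are genes x samples with log-normalized values (the package never normalizes);
clinical tables carry overall survival plus the dichotomized covariates used
for Cox modelling. Readers validate and reject malformed input rather than
coercing it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25

SAMPLE_GROUPS = ("tumor", "normal")

#: Categorical clinical covariates and their admissible levels. The first
#: level of each pair is the Cox reference level; trailing levels such as
#: "NX"/"MX"/"unknown" denote missing information and are excluded listwise
#: from model fits.
CLINICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("younger", "older"),
    "gender": ("female", "male"),
    "grade_group": ("G1&2", "G3&4"),
    "stage_group": ("I&II", "III&IV"),
    "t_group": ("T1&2", "T3&4"),
    "n_status": ("N0", "N1", "NX"),
    "m_status": ("M0", "M1", "MX"),
    "hemoglobin": ("normal", "low", "unknown"),
    "platelet": ("normal", "elevated", "unknown"),
    "calcium": ("normal", "low", "unknown"),
}

REQUIRED_CLINICAL_COLUMNS = ("os_time", "os_event") + tuple(CLINICAL_LEVELS)


class MpsValidationError(ValueError):
    """Invalid input data or configuration."""


class MpsParseError(MpsValidationError):
    """Malformed file content."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise MpsValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log-scale expression with tumor/normal sample labels."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    sample_group: pd.Series  # index = sample ids, values in SAMPLE_GROUPS

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise MpsValidationError("values must be a DataFrame")
        _check_unique(self.values.index.astype(str), "gene symbol")
        _check_unique(self.values.columns.astype(str), "sample id")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise MpsValidationError("expression values must be finite")
        self.sample_group = pd.Series(self.sample_group, dtype=object)
        if not self.sample_group.index.equals(self.values.columns):
            self.sample_group = self.sample_group.reindex(self.values.columns)
        if self.sample_group.isna().any():
            missing = self.sample_group.index[self.sample_group.isna()].tolist()
            raise MpsValidationError(f"samples without group label: {missing[:5]}")
        bad = set(self.sample_group.unique()) - set(SAMPLE_GROUPS)
        if bad:
            raise MpsValidationError(f"unknown sample group labels: {sorted(bad)}")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tumor_ids(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == "tumor"])

    def normal_ids(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == "normal"])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)], self.sample_group.loc[list(sample_ids)]
        )


@dataclass
class ClinicalTable:
    """Per-sample overall survival and dichotomized clinical covariates.

    os_time is stored in days internally.
    """

    table: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise MpsValidationError(f"missing required clinical column(s): {missing}")
        _check_unique(df.index.astype(str), "sample id")
        if len(df):
            t = pd.to_numeric(df["os_time"], errors="raise")
            if (t < 0).any():
                raise MpsValidationError("os_time must be nonnegative")
            ev = df["os_event"]
            if not ev.isin([0, 1]).all():
                raise MpsValidationError("os_event must be 0 or 1")
            for col, levels in CLINICAL_LEVELS.items():
                bad = set(df[col].astype(str).unique()) - set(levels)
                if bad:
                    raise MpsValidationError(
                        f"unknown level(s) for {col!r}: {sorted(bad)} (allowed {levels})"
                    )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def os_time(self) -> pd.Series:
        return self.table["os_time"].astype(float)

    @property
    def os_event(self) -> pd.Series:
        return self.table["os_event"].astype(int)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])


def encode_covariates(clinical: ClinicalTable, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """0/1 design columns for the dichotomized covariates.

    Non-reference level -> 1; missing-information levels (NX, MX, unknown)
    -> NaN so that model fits can delete them listwise.
    """
    variables = list(variables) if variables is not None else list(CLINICAL_LEVELS)
    out = {}
    for var in variables:
        if var not in CLINICAL_LEVELS:
            raise MpsValidationError(f"unknown clinical variable: {var!r}")
        ref, alt = CLINICAL_LEVELS[var][0], CLINICAL_LEVELS[var][1]
        col = clinical.table[var].astype(str)
        enc = pd.Series(np.nan, index=col.index, dtype=float)
        enc[col == ref] = 0.0
        enc[col == alt] = 1.0
        out[var] = enc
    return pd.DataFrame(out, index=clinical.table.index)


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    score_high: int
    score_low: int
    weight: float

    def __post_init__(self) -> None:
        if self.score_high not in (0, 1) or self.score_low not in (0, 1):
            raise MpsValidationError(f"{self.symbol}: score_high/score_low must be 0 or 1")
        if self.score_high + self.score_low != 1:
            raise MpsValidationError(
                f"{self.symbol}: exactly one of score_high/score_low must be 1"
            )
        if not (self.weight > 0 and np.isfinite(self.weight)):
            raise MpsValidationError(f"{self.symbol}: weight must be a positive finite number")


@dataclass
class GenePanel:
    """A gene signature: per gene the favorable expression state and a weight.

    score_high = 1 means expression above the median cutoff scores 1 (the
    prognostically favorable state); score_low = 1 means at-or-below median
    scores 1. The maximum possible score is the sum of the weights.
    """

    entries: list[PanelGene]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise MpsValidationError("empty panel")
        _check_unique((e.symbol for e in self.entries), "panel gene")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    @property
    def weights(self) -> pd.Series:
        return pd.Series({e.symbol: e.weight for e in self.entries}).loc[self.symbols]

    @property
    def max_score(self) -> float:
        return float(sum(e.weight for e in self.entries))

    def entry(self, symbol: str) -> PanelGene:
        for e in self.entries:
            if e.symbol == symbol:
                return e
        raise KeyError(symbol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.entries],
        ).set_index("symbol")


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MpsParseError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise MpsParseError(f"empty file: {path}")
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MpsParseError(f"cannot parse {path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write expression TSV plus a companion `<path>.groups.tsv` label file."""
    path = Path(path)
    df = matrix.values.copy()
    df.index.name = "symbol"
    df.to_csv(path, sep="\t")
    groups = matrix.sample_group.rename("group").to_frame()
    groups.index.name = "sample_id"
    groups.to_csv(_groups_path(path), sep="\t")


def _groups_path(path: Path) -> Path:
    return path.with_name(path.name + ".groups.tsv")


def read_expression(path: str | Path, groups_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbol, header = sample ids).

    Tumor/normal labels come from `groups_path` (default: `<path>.groups.tsv`
    if present). Without a label file every sample is labeled "tumor", which
    is the common case for a scoring-only cohort.
    """
    path = Path(path)
    df = _read_tsv(path)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise MpsParseError(f"duplicate gene symbol(s) in {path}: {dup}")
    dupc = df.columns[df.columns.duplicated()].unique().tolist()
    if dupc:
        raise MpsParseError(f"duplicate sample id(s) in {path}: {dupc}")
    for i, col in enumerate(df.columns):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(df.index.get_loc(bad.index[0])) + 2  # +1 header, +1 1-based
            raise MpsParseError(
                f"non-numeric cell in {path}, column {col!r}, line {line}"
            ) from exc
    if groups_path is None and _groups_path(path).exists():
        groups_path = _groups_path(path)
    if groups_path is not None:
        g = _read_tsv(groups_path)
        if "group" not in g.columns:
            raise MpsParseError(f"{groups_path}: expected a 'group' column")
        groups = g["group"].astype(str).reindex(df.columns)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])[:5]
            raise MpsParseError(f"{groups_path}: missing group label for {missing}")
    else:
        groups = pd.Series("tumor", index=df.columns)
    return ExpressionMatrix(df.astype(float), groups)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_clinical(path: str | Path, time_unit: str = "days") -> ClinicalTable:
    """Read a clinical TSV. os_time in `time_unit` ("days" or "months")."""
    df = _read_tsv(path)
    df.index.name = "sample_id"
    df.index = df.index.astype(str)
    if "os_time" in df.columns:
        if time_unit == "months":
            df["os_time"] = pd.to_numeric(df["os_time"]) * DAYS_PER_MONTH
        elif time_unit != "days":
            raise MpsValidationError(f"unknown time unit: {time_unit!r}")
    return ClinicalTable(df)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "provenance": panel.provenance,
            "entries": [dataclasses.asdict(e) for e in panel.entries],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        df = panel.to_frame()
        df.to_csv(path, sep="\t")


def read_panel(path: str | Path) -> GenePanel:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        entries = [PanelGene(**e) for e in payload["entries"]]
        return GenePanel(entries, provenance=payload.get("provenance", ""))
    df = _read_tsv(path)
    needed = {"score_high", "score_low", "weight"}
    if not needed.issubset(df.columns):
        raise MpsParseError(f"panel file {path} missing column(s): {sorted(needed - set(df.columns))}")
    entries = [
        PanelGene(str(sym), int(row["score_high"]), int(row["score_low"]), float(row["weight"]))
        for sym, row in df.iterrows()
    ]
    return GenePanel(entries, provenance=str(path))


def load_published_panel() -> GenePanel:
    """The published 21-gene ccRCC mPS panel (favorable state + weight per gene)."""
    from importlib.resources import files

    path = files("mpscore").joinpath("data/panel_ccrcc21.tsv")
    with path.open("r") as fh:  # type: ignore[call-arg]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    entries = [
        PanelGene(str(sym), int(r["score_high"]), int(r["score_low"]), float(r["weight"]))
        for sym, r in df.iterrows()
    ]
    return GenePanel(entries, provenance="published 21-gene ccRCC mPS panel")


def write_scores(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-sample scores (columns: mps and, if present, stratum)."""
    df = results.copy()
    df.index.name = "sample_id"
    cols = [c for c in ("mps", "stratum") if c in df.columns]
    df[cols].to_csv(path, sep="\t")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "mps" not in df.columns:
        raise MpsParseError(f"scores file {path} missing 'mps' column")
    return df


def align_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable, mode: str = "strict"
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Join expression tumor samples with clinical rows on sample_id.

    strict: any unmatched id on either side is an error. intersect: keep the
    common ids and report the dropped ones in the raised-or-logged message.
    """
    import logging

    tumor = set(expr.tumor_ids())
    clin = set(clinical.sample_ids)
    only_expr = sorted(tumor - clin)
    only_clin = sorted(clin - tumor)
    if mode == "strict":
        if only_expr or only_clin:
            raise MpsValidationError(
                "unmatched sample ids between expression and clinical data: "
                f"expression-only={only_expr[:5]}, clinical-only={only_clin[:5]}"
            )
    elif mode == "intersect":
        if only_expr or only_clin:
            logging.getLogger(__name__).warning(
                "dropping unmatched samples: %d expression-only, %d clinical-only",
                len(only_expr), len(only_clin),
            )
    else:
        raise MpsValidationError(f"unknown alignment mode: {mode!r}")
    common = [s for s in expr.tumor_ids() if s in clin]
    return expr.subset_samples(common + expr.normal_ids()), clinical.subset(common)
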