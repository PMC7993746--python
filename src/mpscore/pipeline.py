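"""End-to-end pipeline stages with manifests, seeds and logging.

Each stage reads the previous stage's declared files from a run directory,
writes its own outputs plus a `manifest_<stage>.json` (inputs, config hash,
seed, package version, record counts), and is deterministic under a fixed
RunConfig. The single global seed is expanded into independent per-stage
seeds through numpy's SeedSequence([seed, stage_index]).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    CLINICAL_LEVELS,
    ClinicalTable,
    ExpressionMatrix,
    GenePanel,
    MpsValidationError,
    read_clinical,
    read_expression,
    read_panel,
    read_scores,
    write_clinical,
    write_expression,
    write_panel,
    write_scores,
)
from .panel import (
    NnConfig,
    RfConfig,
    assign_gene_scores,
    build_panel,
    extract_gene_weights,
    rf_select_features,
    train_nn,
)
from .scoring import MedianReference, StratificationScheme, score_cohort
from .screen import differential_expression, intersect_prognostic_de, screen_survival
from .simulate import SimulationConfig, generate_cohort, three_year_labels
from .survival import build_nomogram, calibration, concordance_index, cox_screen, km_logrank

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "build-panel", "score", "evaluate")


@dataclass
class RunConfig:
    """Flat pipeline configuration; file values are overridden by CLI flags."""

    out: str = "mps_run"
    seed: int = 0
    # simulate
    n_tumor: int = 400
    n_normal: int = 60
    n_genes: int = 300
    n_prognostic: int = 25
    n_de: int = 60
    planted_log_hr: float = float(np.log(2.0))
    planted_log2fc: float = 2.5
    censor_rate: float = 0.4
    noise_sd: float = 1.0
    n_risk_programs: int = 5
    # screen
    alpha: float = 0.05
    de_alpha: float = 0.05
    de_log2fc: float = 2.0
    # panel construction
    rf_trees: int = 500
    rf_max_depth: int = 10
    rf_folds: int = 10
    rf_top_k: int | None = 21
    rf_importance_cutoff: float | None = None
    nn_epochs: int = 1000
    nn_learning_rate: float = 0.001
    weight_reduction: str = "l1"
    label_horizon_years: float = 3.0
    # scoring / evaluation
    strata: str = "q:0.3333,0.6667"
    horizons: tuple[float, ...] = (3.0, 5.0)
    n_boot: int = 0
    plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MpsValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "horizons" in data:
            data["horizons"] = tuple(float(h) for h in data["horizons"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([int(self.seed), idx])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def parse_strata(text: str, scores=None) -> StratificationScheme:
    """"22,30" = fixed thresholds; "q:0.33,0.66" = score quantiles."""
    text = text.strip()
    if text.startswith("q:"):
        qs = [float(x) for x in text[2:].split(",") if x]
        if scores is None:
            raise MpsValidationError("quantile strata need scores to derive thresholds from")
        labels = ("low", "high") if len(qs) == 1 else ("low", "median", "high")
        return StratificationScheme.from_quantiles(scores, qs, labels)
    thresholds = tuple(float(x) for x in text.split(",") if x)
    labels = ("low", "high") if len(thresholds) == 1 else ("low", "median", "high")
    if len(thresholds) + 1 != len(labels):
        raise MpsValidationError(f"cannot label {len(thresholds)} thresholds")
    return StratificationScheme(thresholds, labels)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MpsValidationError(
            f"missing upstream artifact {path}; produce it with `mpscore {producer}`"
        )
    return path


def _write_manifest(outdir: Path, stage: str, config: RunConfig, inputs: list[str],
                    outputs: list[str], counts: dict) -> None:
    manifest = {
        "stage": stage,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seed": config.stage_seed(stage),
        "version": __version__,
        "counts": counts,
    }
    path = outdir / f"manifest_{stage.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("%s: %s", stage, json.dumps(counts, sort_keys=True))


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(
        n_tumor=config.n_tumor,
        n_normal=config.n_normal,
        n_genes=config.n_genes,
        n_prognostic=config.n_prognostic,
        n_de=config.n_de,
        planted_log_hr=config.planted_log_hr,
        planted_log2fc=config.planted_log2fc,
        censor_rate=config.censor_rate,
        noise_sd=config.noise_sd,
        n_risk_programs=config.n_risk_programs,
        seed=config.stage_seed("simulate"),
    )
    expr, clinical, truth = generate_cohort(sim)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(expr, paths["expression"])
    write_clinical(clinical, paths["clinical"])
    truth.to_json(paths["truth"])
    _write_manifest(
        outdir, "simulate", config, [], [str(p) for p in paths.values()],
        {"n_tumor": expr.sample_group.eq("tumor").sum().item(),
         "n_normal": expr.sample_group.eq("normal").sum().item(),
         "n_genes": expr.n_genes},
    )
    return paths


def stage_screen(config: RunConfig) -> dict[str, Path]:
    outdir = Path(config.out)
    expr = read_expression(_require(outdir / "expression.tsv", "simulate"))
    clinical = read_clinical(_require(outdir / "clinical.tsv", "simulate"))
    screen = screen_survival(expr, clinical, alpha=config.alpha)
    de = differential_expression(expr, alpha=config.de_alpha, log2fc_cutoff=config.de_log2fc)
    candidates = intersect_prognostic_de(screen, de)
    paths = {
        "survival_screen": outdir / "survival_screen.tsv",
        "de_results": outdir / "de_results.tsv",
        "candidates": outdir / "candidates.txt",
    }
    screen.table.to_csv(paths["survival_screen"], sep="\t")
    de.to_csv(paths["de_results"], sep="\t")
    paths["candidates"].write_text("\n".join(candidates) + ("\n" if candidates else ""))
    counts = {
        "genes_screened": int(len(screen.table)),
        "survival_hits": int(len(screen.passing)),
        "de_hits": int(de["passes"].sum()),
        "candidates": len(candidates),
    }
    (outdir / "screen_summary.json").write_text(json.dumps(counts, indent=2, sort_keys=True) + "\n")
    _write_manifest(
        outdir, "screen", config,
        [str(outdir / "expression.tsv"), str(outdir / "clinical.tsv")],
        [str(p) for p in paths.values()], counts,
    )
    return paths


def stage_build_panel(config: RunConfig) -> dict[str, Path]:
    outdir = Path(config.out)
    expr = read_expression(_require(outdir / "expression.tsv", "simulate"))
    clinical = read_clinical(_require(outdir / "clinical.tsv", "simulate"))
    screen_table = pd.read_csv(
        _require(outdir / "survival_screen.tsv", "screen"), sep="\t", index_col=0
    )
    candidates = [
        line.strip()
        for line in _require(outdir / "candidates.txt", "screen").read_text().splitlines()
        if line.strip()
    ]
    if not candidates:
        raise MpsValidationError("no candidate genes passed the screen; cannot build a panel")
    seed = config.stage_seed("build-panel")
    tumor_expr = expr.values[expr.tumor_ids()]
    scores, directions, cutoffs = assign_gene_scores(tumor_expr, screen_table, candidates)
    labels = three_year_labels(clinical, years=config.label_horizon_years)
    rf_cfg = RfConfig(
        n_trees=config.rf_trees,
        max_depth=config.rf_max_depth,
        n_folds=config.rf_folds,
        importance_cutoff=config.rf_importance_cutoff if config.rf_importance_cutoff is not None else 0.5,
        top_k=config.rf_top_k if config.rf_importance_cutoff is None else None,
        seed=seed,
    )
    importances = rf_select_features(scores, labels, rf_cfg)
    selected = list(importances.index[importances["selected"]])
    if not selected:
        raise MpsValidationError("random forest selected no genes; lower the cutoff or use top_k")
    nn_cfg = NnConfig(epochs=config.nn_epochs, learning_rate=config.nn_learning_rate, seed=seed)
    model = train_nn(scores.loc[selected], labels, nn_cfg)
    weights = extract_gene_weights(model, reduction=config.weight_reduction)
    panel = build_panel(
        selected, directions, weights,
        provenance=f"built by mpscore {__version__}, config {config.config_hash()}",
    )
    paths = {
        "panel": outdir / "panel.tsv",
        "medians": outdir / "medians.tsv",
        "provenance": outdir / "panel_provenance.json",
    }
    write_panel(panel, paths["panel"])
    cutoffs.loc[panel.symbols].rename("cutoff").to_frame().rename_axis("symbol").to_csv(
        paths["medians"], sep="\t"
    )
    prov = {
        "rf_config": dataclasses.asdict(rf_cfg),
        "nn_config": dataclasses.asdict(nn_cfg),
        "weight_reduction": config.weight_reduction,
        "n_training_samples": int(len(labels)),
        "loss_first": float(model.training_loss_trace[0]),
        "loss_final": float(model.training_loss_trace[-1]),
        "importances": {s: float(v) for s, v in importances["importance"].items()},
        "selected": selected,
    }
    paths["provenance"].write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    _write_manifest(
        outdir, "build-panel", config,
        [str(outdir / p) for p in ("expression.tsv", "clinical.tsv", "survival_screen.tsv", "candidates.txt")],
        [str(p) for p in paths.values()],
        {"candidates": len(candidates), "panel_size": len(panel),
         "training_samples": int(len(labels))},
    )
    return paths


def stage_score(
    config: RunConfig,
    expression_path: str | Path | None = None,
    panel_path: str | Path | None = None,
    use_reference_medians: bool = False,
) -> dict[str, Path]:
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = Path(expression_path) if expression_path else _require(outdir / "expression.tsv", "simulate")
    pnl_path = Path(panel_path) if panel_path else _require(outdir / "panel.tsv", "build-panel")
    expr = read_expression(expr_path)
    panel = read_panel(pnl_path)
    medians = None
    if use_reference_medians:
        mpath = _require(outdir / "medians.tsv", "build-panel")
        cut = pd.read_csv(mpath, sep="\t", index_col=0)["cutoff"]
        medians = MedianReference(cutoffs=cut, source=str(mpath))
    raw = score_cohort(expr.subset_samples(expr.tumor_ids()), panel, medians=medians, scheme=None)
    scheme = parse_strata(config.strata, scores=raw["mps"].to_numpy())
    results = raw.copy()
    results["stratum"] = scheme.assign(results["mps"])
    paths = {"scores": outdir / "scores.tsv", "strata": outdir / "strata_summary.json"}
    write_scores(results, paths["scores"])
    summary = {
        "thresholds": list(scheme.thresholds),
        "labels": list(scheme.labels),
        "counts": {k: int(v) for k, v in results["stratum"].value_counts().items()},
        "mps_min": float(results["mps"].min()),
        "mps_max": float(results["mps"].max()),
        "panel_max_score": panel.max_score,
    }
    paths["strata"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write_manifest(
        outdir, "score", config, [str(expr_path), str(pnl_path)],
        [str(p) for p in paths.values()],
        {"samples_scored": int(len(results)), "panel_size": len(panel)},
    )
    return paths


def stage_evaluate(config: RunConfig) -> dict[str, Path]:
    outdir = Path(config.out)
    scores = read_scores(_require(outdir / "scores.tsv", "score"))
    clinical = read_clinical(_require(outdir / "clinical.tsv", "simulate"))
    scores = scores.loc[[s for s in clinical.sample_ids if s in scores.index]]
    clinical = clinical.subset(list(scores.index))
    seed = config.stage_seed("evaluate")

    curves, chi2, logrank_p = km_logrank(clinical, scores["stratum"])
    # mPS dichotomy for Cox: "high" = any stratum above the lowest
    mps_high = (scores["stratum"] != "low").astype(float).rename("mps_high")
    extra = mps_high.to_frame()
    variables = list(CLINICAL_LEVELS) + ["mps_high"]
    uni, multi = cox_screen(clinical, variables, extra_covariates=extra, alpha=0.05)
    c_mps = concordance_index(scores["mps"], clinical, higher_is="survival")

    report: dict = {
        "logrank": {"chi2": chi2, "p": logrank_p, "groups": sorted(scores["stratum"].unique())},
        "c_index_mps_continuous": c_mps,
        "cox_univariate": {
            v: {**{k: float(f.summary.loc[v, k]) for k in ("beta", "hr", "ci_low", "ci_high", "p")},
                "n_used": f.n_used}
            for v, f in uni.items()
        },
    }
    uni_table = pd.DataFrame({v: f.summary.loc[v] for v, f in uni.items()}).T
    uni_table.to_csv(outdir / "cox_univariate.tsv", sep="\t")
    paths = {"report": outdir / "evaluation.json", "cox_uni": outdir / "cox_univariate.tsv"}
    if multi is not None:
        multi.summary.to_csv(outdir / "cox_multivariate.tsv", sep="\t")
        paths["cox_multi"] = outdir / "cox_multivariate.tsv"
        report["cox_multivariate"] = {
            v: {k: float(multi.summary.loc[v, k]) for k in ("beta", "hr", "ci_low", "ci_high", "p")}
            for v in multi.variables
        }
        report["cox_multivariate_n_used"] = multi.n_used
        nom = build_nomogram(multi, horizons_years=tuple(config.horizons))
        report["nomogram"] = {
            "variables": nom.variables,
            "c_index": nom.c_index,
            "points_per_variable": {
                v: float(abs(nom.betas[v]) * (nom.fit.data[v].max() - nom.fit.data[v].min()) / nom.unit)
                for v in nom.variables
            },
        }
        report["calibration"] = {}
        last_obs_years = float(clinical.os_time.max()) / 365.25
        for h in config.horizons:
            if h >= last_obs_years:
                report["calibration"][f"{h:g}y"] = None
                continue
            cal = calibration(nom, horizon_years=h, n_boot=config.n_boot, seed=seed)
            report["calibration"][f"{h:g}y"] = json.loads(cal.to_json(orient="records"))
            if config.plots:
                from .survival import plot_calibration

                plot_calibration(cal, outdir / f"calibration_{h:g}y.png", f"at {h:g}y")
    if config.plots:
        from .survival import plot_km

        plot_km(curves, outdir / "km_strata.png")
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_manifest(
        outdir, "evaluate", config,
        [str(outdir / "scores.tsv"), str(outdir / "clinical.tsv")],
        [str(p) for p in paths.values()],
        {"samples": int(len(scores)), "strata": int(scores["stratum"].nunique()),
         "multivariate_variables": 0 if multi is None else len(multi.variables)},
    )
    return paths


def run_all(config: RunConfig) -> dict[str, Path]:
    paths = {}
    paths.update(stage_simulate(config))
    paths.update(stage_screen(config))
    paths.update(stage_build_panel(config))
    paths.update(stage_score(config))
    paths.update(stage_evaluate(config))
    return paths
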