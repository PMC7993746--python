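import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpscore import (
    ExpressionMatrix,
    GenePanel,
    MedianReference,
    MpsValidationError,
    PanelGene,
    StratificationScheme,
    compute_mps,
    score_cohort,
    stratify,
)


def _scores(panel: GenePanel, matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        matrix, index=panel.symbols, columns=[f"s{i}" for i in range(matrix.shape[1])]
    )


def test_mps_zero_single_gene_and_full(published_panel):
    n = len(published_panel)
    mat = np.zeros((n, 3), dtype=int)
    mat[published_panel.symbols.index("DDAH1"), 1] = 1
    mat[:, 2] = 1
    res = compute_mps(_scores(published_panel, mat), published_panel)
    assert res["mps"].iloc[0] == 0.0
    assert res["mps"].iloc[1] == pytest.approx(3.580)
    assert res["mps"].iloc[2] == pytest.approx(74.616)


def test_mps_missing_gene_listed(published_panel):
    mat = _scores(published_panel, np.zeros((21, 1), dtype=int)).drop(index=["UBE2C"])
    with pytest.raises(MpsValidationError, match="UBE2C"):
        compute_mps(mat, published_panel)


def test_mps_rejects_non_binary(toy_panel):
    mat = _scores(toy_panel, np.array([[0.5], [0.0], [0.0]]))
    with pytest.raises(MpsValidationError, match="binary"):
        compute_mps(mat, toy_panel)


def _toy_panel() -> GenePanel:
    return GenePanel(
        [PanelGene("A", 1, 0, 2.0), PanelGene("B", 0, 1, 3.0), PanelGene("C", 1, 0, 5.0)]
    )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.data())
def test_mps_additivity_and_monotonicity(data):
    panel = _toy_panel()
    base = np.array(data.draw(st.lists(st.integers(0, 1), min_size=3, max_size=3)))
    gene = data.draw(st.integers(0, 2))
    flipped = base.copy()
    flipped[gene] = 1 - flipped[gene]
    mat = np.column_stack([base, flipped])
    res = compute_mps(_scores(panel, mat), panel)
    delta = res["mps"].iloc[1] - res["mps"].iloc[0]
    weight = panel.entries[gene].weight
    # flipping one gene changes mps by exactly its weight
    assert abs(abs(delta) - weight) < 1e-12
    # dominance: all-ones dominates both pointwise
    top = compute_mps(_scores(panel, np.ones((3, 1), dtype=int)), panel)["mps"].iloc[0]
    assert top >= res["mps"].max() - 1e-12


@pytest.mark.parametrize(
    "mps,expected",
    [(21.99, "low"), (22.0, "median"), (29.99, "median"), (30.0, "high"), (0.0, "low"),
     (74.616, "high")],
)
def test_published_three_group_boundaries(mps, expected):
    scheme = StratificationScheme.published_three_group()
    assert scheme.assign(mps) == expected


def test_published_two_group_boundary():
    scheme = StratificationScheme.published_two_group()
    assert scheme.assign(22.0) == "high"
    assert scheme.assign(21.999) == "low"


def test_scheme_validation():
    with pytest.raises(MpsValidationError, match="label"):
        StratificationScheme((22.0,), ("low", "median", "high"))
    with pytest.raises(MpsValidationError, match="ascending"):
        StratificationScheme((30.0, 22.0), ("a", "b", "c"))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(0, 80, allow_nan=False), min_size=1, max_size=30))
def test_strata_partition(values):
    scheme = StratificationScheme.published_three_group()
    labels = scheme.assign(pd.Series(values))
    assert labels.isin(scheme.labels).all()
    assert labels.value_counts().sum() == len(values)


def test_scale_equivariance(toy_panel):
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 2, (3, 20))
    res = compute_mps(_scores(toy_panel, mat), toy_panel)
    c = 3.7
    scaled_panel = GenePanel(
        [PanelGene(e.symbol, e.score_high, e.score_low, e.weight * c) for e in toy_panel.entries]
    )
    res_c = compute_mps(_scores(scaled_panel, mat), scaled_panel)
    np.testing.assert_allclose(res_c["mps"], res["mps"] * c)
    scheme = StratificationScheme((2.0, 5.0), ("low", "median", "high"))
    scheme_c = StratificationScheme((2.0 * c, 5.0 * c), ("low", "median", "high"))
    pd.testing.assert_series_equal(
        stratify(res, scheme)["stratum"], stratify(res_c, scheme_c)["stratum"]
    )


def test_from_quantiles():
    scores = np.arange(100, dtype=float)
    scheme = StratificationScheme.from_quantiles(scores)
    labels = scheme.assign(pd.Series(scores))
    counts = labels.value_counts()
    assert abs(counts["low"] - counts["high"]) <= 2


def _expr(panel, n=30, seed=0):
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(
        rng.normal(size=(len(panel), n)),
        index=panel.symbols,
        columns=[f"s{i}" for i in range(n)],
    )
    return ExpressionMatrix(vals, pd.Series("tumor", index=vals.columns))


def test_score_cohort_self_consistency(published_panel):
    expr = _expr(published_panel)
    a = score_cohort(expr, published_panel)
    b = score_cohort(expr, published_panel)
    pd.testing.assert_frame_equal(a, b)
    # matches manual dot product with per-cohort medians
    manual = np.zeros(expr.n_samples)
    for e in published_panel.entries:
        v = expr.values.loc[e.symbol]
        high = (v > v.median()).astype(int)
        score = high if e.score_high else 1 - high
        manual += e.weight * score.to_numpy()
    np.testing.assert_allclose(a["mps"], manual)


def test_score_cohort_reference_medians(published_panel):
    expr = _expr(published_panel, seed=1)
    ref = MedianReference(cutoffs=pd.Series(10.0, index=published_panel.symbols), source="ref")
    res = score_cohort(expr, published_panel, medians=ref)
    # all expression < 10 -> every gene in the low state -> sum of score_low weights
    expected = sum(e.weight for e in published_panel.entries if e.score_low == 1)
    np.testing.assert_allclose(res["mps"], expected)


def test_score_cohort_single_sample_all_low(published_panel):
    expr = _expr(published_panel, n=1)
    res = score_cohort(expr, published_panel)
    expected = sum(e.weight for e in published_panel.entries if e.score_low == 1)
    assert res["mps"].iloc[0] == pytest.approx(expected)


def test_score_cohort_missing_gene_modes(published_panel):
    expr = _expr(published_panel)
    one_missing = ExpressionMatrix(expr.values.drop(index=["SIM2"]), expr.sample_group)
    with pytest.raises(MpsValidationError, match="SIM2"):
        score_cohort(one_missing, published_panel, strict=True)
    res = score_cohort(one_missing, published_panel, strict=False)
    # imputed at-median -> low state -> SIM2 (score_low=1) contributes its weight
    full = score_cohort(expr, published_panel, strict=True)
    v = expr.values.loc["SIM2"]
    sim2_scores = (1 - (v > v.median()).astype(int)) * 3.364
    np.testing.assert_allclose(res["mps"], full["mps"] - sim2_scores + 3.364)
    many_missing = ExpressionMatrix(
        expr.values.drop(index=published_panel.symbols[:5]), expr.sample_group
    )
    with pytest.raises(MpsValidationError, match="20%"):
        score_cohort(many_missing, published_panel, strict=False)


def test_scored_strata_separate_survival(small_cohort, published_panel):
    """Held-out scoring: strata from a planted-effect cohort separate survival."""
    from mpscore import SimulationConfig, generate_cohort, km_logrank
    from mpscore.pipeline import parse_strata
    from mpscore.screen import screen_survival
    from mpscore.panel import assign_gene_scores, build_panel

    expr, clinical, truth = small_cohort
    screen = screen_survival(expr, clinical)
    genes = truth.prognostic_genes
    tumor = expr.values[expr.tumor_ids()]
    _, directions, _ = assign_gene_scores(tumor, screen, genes)
    panel = build_panel(genes, directions, pd.Series(1.0, index=genes))
    cfg = SimulationConfig(n_tumor=300, n_normal=0, n_genes=80, n_prognostic=10, n_de=25,
                           censor_rate=0.4, seed=77)
    expr2, clin2, _ = generate_cohort(cfg)
    res = score_cohort(expr2.subset_samples(expr2.tumor_ids()), panel, scheme=None)
    scheme = parse_strata("q:0.5", res["mps"].to_numpy())
    res["stratum"] = scheme.assign(res["mps"])
    _, _, p = km_logrank(clin2, res["stratum"])
    assert p < 0.01
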