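import numpy as np
import pandas as pd
import pytest

from mpscore import (
    MpsValidationError,
    build_nomogram,
    calibration,
    concordance_index,
    cox_multivariate,
    cox_screen,
    cox_univariate,
    km_logrank,
)
from mpscore.io import CLINICAL_LEVELS, ClinicalTable


def _clinical(times, events, **levels):
    n = len(times)
    df = pd.DataFrame({"os_time": times, "os_event": events},
                      index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    for col, lv in CLINICAL_LEVELS.items():
        vals = levels.get(col)
        df[col] = vals if vals is not None else lv[0]
    return ClinicalTable(df)


@pytest.fixture(scope="module")
def driven_cohort(covariate_cohort):
    return covariate_cohort  # expression, clinical, truth


def test_km_identical_groups_null(small_cohort):
    _, clinical, _ = small_cohort
    # duplicate each sample into two groups with identical survival
    df = pd.concat([clinical.table, clinical.table.set_index(clinical.table.index + "_b")])
    doubled = ClinicalTable(df)
    groups = pd.Series(["a"] * len(clinical) + ["b"] * len(clinical), index=df.index)
    curves, chi2, p = km_logrank(doubled, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)
    for c in curves:
        assert c.at(0.0) == 1.0  # before the first event
        assert (np.diff(c.survival) <= 1e-12).all()


def test_km_single_group_rejected(small_cohort):
    _, clinical, _ = small_cohort
    with pytest.raises(MpsValidationError, match="2 groups"):
        km_logrank(clinical, pd.Series("all", index=clinical.sample_ids))


def test_km_uncensored_equals_empirical():
    times = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
    clin = _clinical(times, [1] * 6)
    groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=clin.sample_ids)
    curves, _, _ = km_logrank(clin, groups)
    a = curves[0]
    for t in [5, 10, 25, 30]:
        emp = np.mean(times[:3] > t)
        assert a.at(t) == pytest.approx(emp)


def test_km_separates_different_hazards():
    rng = np.random.default_rng(2)
    t1 = rng.exponential(1.0, 200)
    t2 = rng.exponential(2.0, 200)
    clin = _clinical(np.concatenate([t1, t2]), [1] * 400)
    groups = pd.Series(["fast"] * 200 + ["slow"] * 200, index=clin.sample_ids)
    _, _, p = km_logrank(clin, groups)
    assert p < 1e-6


def test_cox_null_covariate(driven_cohort):
    _, clinical, _ = driven_cohort
    fit = cox_univariate(clinical, "gender")  # no planted effect
    assert fit.summary.loc["gender", "hr"] == pytest.approx(1.0, abs=0.35)
    assert fit.summary.loc["gender", "p"] > 0.05


def test_cox_recovers_planted_effect(driven_cohort):
    _, clinical, truth = driven_cohort
    fit = cox_multivariate(clinical, ["m_status", "stage_group"])
    for var, beta in truth.true_covariate_betas.items():
        assert fit.summary.loc[var, "beta"] == pytest.approx(beta, abs=0.35)
        assert fit.summary.loc[var, "ci_low"] <= fit.summary.loc[var, "hr"] <= fit.summary.loc[var, "ci_high"]
        assert fit.summary.loc[var, "hr"] == pytest.approx(np.exp(fit.summary.loc[var, "beta"]), rel=1e-9)


def test_multivariate_single_equals_univariate(driven_cohort):
    _, clinical, _ = driven_cohort
    uni = cox_univariate(clinical, "m_status")
    multi = cox_multivariate(clinical, ["m_status"])
    assert multi.summary.loc["m_status", "beta"] == pytest.approx(
        uni.summary.loc["m_status", "beta"], abs=1e-8
    )


def test_reference_relabel_negates_beta(driven_cohort):
    _, clinical, _ = driven_cohort
    from mpscore import encode_covariates

    enc = encode_covariates(clinical, ["m_status"])
    flipped = (1.0 - enc).rename(columns={"m_status": "m_flipped"})
    a = cox_multivariate(clinical, ["m_status"])
    b = cox_multivariate(clinical, ["m_flipped"], extra_covariates=flipped)
    assert b.summary.loc["m_flipped", "beta"] == pytest.approx(
        -a.summary.loc["m_status", "beta"], abs=1e-6
    )


def test_listwise_deletion_reported(driven_cohort):
    _, clinical, _ = driven_cohort
    fit = cox_univariate(clinical, "m_status")
    n_known = (clinical.table["m_status"] != "MX").sum()
    assert fit.n_used == n_known < len(clinical)


def test_cox_screen_carry_forward(driven_cohort):
    _, clinical, _ = driven_cohort
    uni, multi = cox_screen(clinical, ["m_status", "stage_group", "gender"])
    assert set(uni) == {"m_status", "stage_group", "gender"}
    assert multi is not None
    assert "gender" not in multi.variables  # null covariate not carried forward
    assert {"m_status", "stage_group"} <= set(multi.variables)


def test_cox_constant_covariate_rejected():
    clin = _clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
    with pytest.raises(MpsValidationError, match="constant"):
        cox_univariate(clin, "gender")


# ---------------------------------------------------------------------------
# concordance


def test_cindex_perfect_reversed_and_ties():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    clin = _clinical(times, [1] * 5)
    risk = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=clin.sample_ids)
    assert concordance_index(risk, clin, higher_is="risk") == 1.0
    assert concordance_index(-risk, clin, higher_is="risk") == 0.0
    assert concordance_index(risk, clin, higher_is="survival") == 0.0
    flat = pd.Series(1.0, index=clin.sample_ids)
    assert concordance_index(flat, clin) == 0.5


def test_cindex_monotone_transform_invariant(driven_cohort):
    _, clinical, _ = driven_cohort
    rng = np.random.default_rng(1)
    score = pd.Series(rng.normal(size=len(clinical)), index=clinical.sample_ids)
    c1 = concordance_index(score, clinical)
    c2 = concordance_index(np.exp(3 * score), clinical)
    assert c1 == pytest.approx(c2, abs=1e-12)


def test_cindex_requires_events():
    clin = _clinical([1.0, 2.0], [0, 0])
    with pytest.raises(MpsValidationError, match="comparable"):
        concordance_index(pd.Series([1.0, 2.0], index=clin.sample_ids), clin)


# ---------------------------------------------------------------------------
# nomogram + calibration


@pytest.fixture(scope="module")
def fitted(driven_cohort):
    _, clinical, _ = driven_cohort
    fit = cox_multivariate(clinical, ["m_status", "stage_group", "age_group"])
    return fit, build_nomogram(fit)


def test_nomogram_point_normalization(fitted):
    fit, nom = fitted
    X = fit.data[fit.variables]
    pts = nom.points(X)
    spans = pts.max() - pts.min()
    assert spans.max() == pytest.approx(100.0)
    # spans proportional to |beta| * observed range
    betas = fit.summary["beta"].abs()
    ranges = X.max() - X.min()
    expected = 100 * (betas * ranges) / (betas * ranges).max()
    np.testing.assert_allclose(spans.to_numpy(), expected.to_numpy(), atol=1e-9)


def test_nomogram_round_trip_matches_cox(fitted):
    fit, nom = fitted
    X = fit.data[fit.variables]
    direct = fit.predict_survival(X, np.asarray(nom.horizons))
    for hi, horizon in enumerate(nom.horizons):
        via_points = nom.predict_survival_from_points(nom.total_points(X), horizon)
        np.testing.assert_allclose(via_points, direct.iloc[hi].to_numpy(), atol=1e-6)


def test_nomogram_baseline_identity(fitted):
    fit, nom = fitted
    zero = pd.DataFrame([dict.fromkeys(fit.variables, 0.0)])
    s0 = fit.baseline_survival(np.asarray(nom.horizons))
    lp0 = nom.linear_predictor_from_points(nom.total_points(zero))
    np.testing.assert_allclose(lp0, 0.0, atol=1e-12)
    np.testing.assert_allclose(nom.predict_survival(zero, nom.horizons[0]), s0[0], atol=1e-12)


def test_nomogram_requires_multivariate(driven_cohort):
    _, clinical, _ = driven_cohort
    fit = cox_univariate(clinical, "m_status")
    with pytest.raises(MpsValidationError, match="multivariate"):
        build_nomogram(fit)


def test_calibration_contract(fitted):
    _, nom = fitted
    apparent = calibration(nom, horizon_years=3.0, n_boot=0)
    assert {"predicted", "observed", "n", "error"} <= set(apparent.columns)
    assert "observed_adjusted" not in apparent.columns
    assert apparent["n"].sum() == nom.fit.n_used
    boot = calibration(nom, horizon_years=3.0, n_boot=5, seed=3)
    assert "observed_adjusted" in boot.columns
    np.testing.assert_allclose(boot["predicted"], apparent["predicted"])


def test_calibration_horizon_beyond_followup(fitted):
    _, nom = fitted
    with pytest.raises(MpsValidationError, match="horizon"):
        calibration(nom, horizon_years=1e5, n_boot=0)
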