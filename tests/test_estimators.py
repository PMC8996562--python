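"""Estimators: closed-form identities, instrument arithmetic,
statsmodels cross-checks, bias directions and interval calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prefiv as pv
from prefiv.simulate import Scenario
from conftest import make_table, two_by_two_table


# -- instrument construction ------------------------------------------------


def test_plain_instrument_is_hospital_proportion():
    t = make_table([("A", 1, 0), ("A", 1, 1), ("A", 1, 0), ("A", 0, 1), ("B", 0, 0), ("B", 1, 1)])
    z = pv.build_instrument(t)
    assert np.allclose(z.values[:4], 0.75)
    assert np.allclose(z.values[4:], 0.5)


def test_leave_one_out_instrument():
    t = make_table([("A", 1, 0), ("A", 1, 1), ("A", 1, 0), ("A", 0, 1), ("B", 0, 0), ("B", 1, 1)])
    z = pv.build_instrument(t, leave_one_out=True)
    assert np.allclose(z.values[:3], 2 / 3)  # treated patients of A
    assert z.values[3] == pytest.approx(1.0)  # untreated patient of A
    assert z.values[4] == pytest.approx(1.0) and z.values[5] == pytest.approx(0.0)


def test_leave_one_out_rejects_singleton_hospital():
    t = make_table([("A", 1, 0), ("A", 0, 1), ("B", 1, 1)])
    with pytest.raises(pv.EstimationError):
        pv.build_instrument(t, leave_one_out=True)


def test_instrument_volume_weighted_mean_is_overall_rate(ivt_registry):
    table, _ = ivt_registry
    z = pv.build_instrument(table)
    assert z.values.mean() == pytest.approx(table.df["treated"].mean(), abs=1e-12)


# -- individual-level estimators --------------------------------------------


def test_unadjusted_logistic_equals_cross_product_or():
    t = two_by_two_table(80, 40, 35, 60, n_hospitals=3)
    r = pv.estimate_individual_logistic(t, adjusted=False)
    assert r.estimate == pytest.approx((80 * 60) / (40 * 35), rel=1e-8)
    assert r.scale == "odds_ratio" and r.ci_low <= r.estimate <= r.ci_high


def test_gee_single_hospital_equals_logistic():
    t = two_by_two_table(60, 30, 25, 45, n_hospitals=1)
    with pytest.raises((pv.ClusterError, pv.EstimationError)):
        pv.estimate_gee(t, adjusted=False)
    # with clusters but no within-cluster pairs, GEE == logistic
    t2 = two_by_two_table(60, 30, 25, 45, n_hospitals=160, seed=1)
    g = pv.estimate_gee(t2, adjusted=False)
    l = pv.estimate_individual_logistic(t2, adjusted=False)
    assert g.extra["rho"] == 0.0
    assert g.extra["log_or"] == pytest.approx(l.extra["log_or"], abs=1e-8)


def test_logistic_ci_coverage_under_null():
    sc = Scenario(
        volume_range=(300, 900),
        preference_range=(0.3, 0.7),
        beta_treat=0.0,
        gamma={"age": -0.01, "nihss": 0.02},
        theta={"age": -0.04, "nihss": -0.1},
        seed=0,
    )
    covered = 0
    reps = 150
    for r in range(reps):
        t, _ = pv.generate_registry(sc.replace(seed=40_000 + r), with_truth=False)
        res = pv.estimate_individual_logistic(t, adjusted=True)
        covered += res.ci_low <= 1.0 <= res.ci_high
    # binomial(150, .95) three-sigma band
    assert 0.90 <= covered / reps <= 0.99


def test_confounding_by_indication_biases_naive_or():
    sc = Scenario(
        volume_range=(4000, 4000),
        preference_range=(0.3, 0.7),
        beta_treat=0.0,
        delta=0.8,
        phi=-0.8,  # delta*phi < 0: naive OR pushed below 1
        seed=31,
    )
    t, _ = pv.generate_registry(sc, with_truth=False)
    r = pv.estimate_individual_logistic(t, adjusted=True)
    assert r.estimate < 0.9


def test_gee_close_to_logistic_without_cluster_effects(ivt_registry):
    table, _ = ivt_registry
    g = pv.estimate_gee(table, adjusted=True)
    l = pv.estimate_individual_logistic(table, adjusted=True)
    assert g.estimate == pytest.approx(l.estimate, rel=0.01)


def test_gee_diverges_from_logistic_with_hospital_outcome_effects():
    sc = pv.make_ga_like_scenario(seed=8).replace(
        volume_range=(200, 600), hospital_outcome_sd=0.6, hospital_outcome_pref_effect=0.8
    )
    t, _ = pv.generate_registry(sc, with_truth=False)
    g = pv.estimate_gee(t, adjusted=True)
    l = pv.estimate_individual_logistic(t, adjusted=True)
    assert g.extra["rho"] > 0.01
    assert abs(np.log(g.estimate) - np.log(l.estimate)) > 0.05


# -- ecological --------------------------------------------------------------


def test_ecological_two_point_slope():
    rows = []
    # hospital A: 0% treated, 30% good (n=100); B: 100% treated, 40% good (n=100)
    rows += [("A", 0, 1)] * 30 + [("A", 0, 0)] * 70
    rows += [("B", 1, 1)] * 40 + [("B", 1, 0)] * 60
    rows += [("C", 1, 1)] * 35 + [("C", 1, 0)] * 65  # third hospital, also 100%
    t = make_table(rows)
    r = pv.estimate_ecological(t, adjusted=False)
    # weighted LS through (0,30), (100,40), (100,35): slope = (37.5-30)/100
    assert r.estimate == pytest.approx(0.075, abs=1e-10)
    assert r.scale == "percentage_point_per_1pct"


def test_ecological_unidentified_when_utilization_constant():
    rows = [("A", 1, 1), ("A", 1, 0), ("B", 1, 1), ("B", 1, 0), ("C", 1, 0), ("C", 1, 1)]
    with pytest.raises(pv.EstimationError):
        pv.estimate_ecological(make_table(rows), adjusted=False)


def test_ecological_warns_when_few_hospitals_per_parameter(ivt_registry):
    table, _ = ivt_registry
    with pytest.warns(UserWarning, match="hospital-level observations"):
        pv.estimate_ecological(table, adjusted=True)


def test_ecological_recovers_rd_under_pure_practice_variation():
    # no patient-level confounding at all: ecological slope ~ marginal RD
    sc = Scenario(
        volume_range=(5000, 5000),
        preference_range=(0.1, 0.9),
        beta_treat=0.35,
        seed=17,
    )
    t, truth = pv.generate_registry(sc)
    r = pv.estimate_ecological(t, adjusted=False)
    assert r.estimate == pytest.approx(truth.marginal_rd, abs=0.02)


# -- IV estimators -----------------------------------------------------------


def test_iv_linear_equals_wald_ratio():
    rng = np.random.default_rng(44)
    n = 800
    z = rng.integers(0, 2, n)
    t = ((z + rng.random(n)) > 0.8).astype(int)
    y = (rng.random(n) < 0.3 + 0.2 * t).astype(int)
    df = pd.DataFrame({"hospital_id": np.where(z == 1, "A", "B"), "treated": t, "good_outcome": y})
    table = make_table(list(df.itertuples(index=False, name=None)))
    r = pv.estimate_iv_linear(table, adjusted=False)
    wald = np.cov(y, z)[0, 1] / np.cov(t, z)[0, 1]
    assert r.estimate == pytest.approx(wald, abs=1e-10)
    assert r.scale == "risk_difference"


def test_iv_linear_matches_statsmodels_2sls(ivt_registry):
    from statsmodels.sandbox.regression.gmm import IV2SLS

    table, _ = ivt_registry
    df = table.df
    z = pv.build_instrument(table).values
    exog = np.column_stack([np.ones(len(df)), df["treated"]])
    instr = np.column_stack([np.ones(len(df)), z])
    ref = IV2SLS(df["good_outcome"].astype(float), exog, instrument=instr).fit()
    r = pv.estimate_iv_linear(table, adjusted=False)
    assert r.estimate == pytest.approx(np.asarray(ref.params)[1], abs=1e-8)


def test_iv_constant_instrument_errors():
    rows = [("A", 1, 1), ("A", 1, 0), ("B", 1, 1), ("B", 1, 0)] * 5
    t = make_table(rows)
    with pytest.raises(pv.EstimationError):
        pv.estimate_iv_two_stage(t, adjusted=False)
    with pytest.raises(pv.EstimationError):
        pv.estimate_iv_linear(t, adjusted=False)


def test_two_stage_bootstrap_ci_brackets_estimate(ivt_registry):
    table, _ = ivt_registry
    r = pv.estimate_iv_two_stage(table, adjusted=True, ci="bootstrap", n_boot=100, seed=2)
    assert r.ci_low <= r.estimate <= r.ci_high
    assert r.flags["strength_ok"]
    assert r.flags["n_boot_ok"] >= 50


def test_iv_covers_null_when_naive_does_not():
    # unmeasured confounding, true null: the IV interval should cover 1
    # while naive logistic excludes it, in a majority of replicates
    sc = Scenario(
        volume_range=(1500, 3000),
        preference_range=(0.1, 0.9),
        beta_treat=0.0,
        delta=0.9,
        phi=-0.9,
        seed=0,
    )
    iv_covers, naive_excludes = 0, 0
    reps = 20
    for r in range(reps):
        t, _ = pv.generate_registry(sc.replace(seed=60_000 + r), with_truth=False)
        iv = pv.estimate_iv_two_stage(t, adjusted=False, ci="analytic")
        nv = pv.estimate_individual_logistic(t, adjusted=False)
        iv_covers += iv.ci_low <= 1.0 <= iv.ci_high
        naive_excludes += not (nv.ci_low <= 1.0 <= nv.ci_high)
    assert iv_covers > reps / 2
    assert naive_excludes > reps / 2


# -- diagnostics -------------------------------------------------------------


def test_f_statistic_formula_values():
    assert pv.f_statistic(0.5, 102, 1) == pytest.approx(100.0)
    assert pv.f_statistic(0.0, 500, 1) == 0.0


def test_diagnostics_fields(ivt_registry):
    table, _ = ivt_registry
    d = pv.iv_diagnostics(table, pv.build_instrument(table), adjusted=True)
    assert 0 <= d.partial_r2 < 1
    assert d.f_statistic >= 0
    assert 0 <= d.dwh_p <= 1
    assert set(d.confounder_assoc["covariate"]) == set(pv.CASE_MIX)
    assert d.f_n == len(table) and d.f_k == 1


def test_f_above_ten_with_wide_preference_spread():
    sc = Scenario(volume_range=(23, 405), preference_range=(0.4, 0.6), seed=2)
    t, _ = pv.generate_registry(sc, with_truth=False)
    d = pv.iv_diagnostics(t, pv.build_instrument(t), adjusted=False)
    assert d.strength_ok  # >= 20 pp spread at default volumes


def test_dwh_detects_strong_endogeneity():
    sc = Scenario(
        volume_range=(2000, 4000),
        preference_range=(0.1, 0.9),
        beta_treat=0.0,
        delta=1.2,
        phi=-1.2,
        seed=5,
    )
    t, _ = pv.generate_registry(sc, with_truth=False)
    d = pv.iv_diagnostics(t, pv.build_instrument(t), adjusted=False)
    assert d.endogeneity_detected
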