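"""Tests for cross-cohort validation, stratification, adjustment and
risk-direction consistency."""

import numpy as np
import pandas as pd
import pytest

from lncrisk import (
    CohortBundle,
    RiskModel,
    SimulationConfig,
    compute_risk_scores,
    evaluate_signature,
    fit_risk_model,
    multivariate_adjust,
    risk_direction_consistency,
    simulate_study,
    stratify,
    transfer_assignment,
    validate_refit,
    validate_transfer,
)
from conftest import make_bundle


@pytest.fixture(scope="module")
def trained(planted_study):
    train = planted_study.cohorts[0]
    tf = planted_study.config.planted_tfs[0]
    model = fit_risk_model(train, tf, planted_study.network_truth[tf])
    return planted_study, train, model


def test_refit_on_training_cohort_is_identity(trained):
    study, train, model = trained
    ev = validate_refit(model.tf_id, model.lnc_ids, train)
    direct = evaluate_signature(model, train)
    assert ev.logrank.chi2 == pytest.approx(direct.logrank.chi2)
    assert ev.hr_per_sd == pytest.approx(direct.hr_per_sd)


def test_refit_validates_on_independent_cohort(trained):
    study, train, model = trained
    ev = validate_refit(model.tf_id, model.lnc_ids, study.cohorts[1])
    assert ev.logrank_p < 0.05
    assert ev.hr_per_sd > 1


def test_transfer_fixed_point_reproduces_training_split(trained):
    study, train, model = trained
    direct = evaluate_signature(model, train)
    transferred = validate_transfer(model, train, training=train)
    assert np.array_equal(direct.assignment.group, transferred.assignment.group)


def test_transfer_invariant_to_global_affine_expression_map(trained):
    study, train, model = trained
    val = study.cohorts[1]
    base = transfer_assignment(
        model, val, compute_risk_scores(model, train.expression).to_numpy()
    )
    warped = CohortBundle(val.expression * 2.0 + 5.0, val.survival, name=val.name)
    mapped = transfer_assignment(
        model, warped, compute_risk_scores(model, train.expression).to_numpy()
    )
    assert np.array_equal(base.group, mapped.group)


def test_transfer_rejects_degenerate_scores(trained):
    study, train, model = trained
    val = study.cohorts[1]
    flat = CohortBundle(val.expression * 0.0, val.survival, name="flat")
    with pytest.raises(ValueError):
        validate_transfer(model, flat, training=train)


# --------------------------------------------------------------- stratify

def _clin_bundle(**covars):
    n = len(next(iter(covars.values())))
    rng = np.random.default_rng(0)
    return make_bundle({"G1": rng.standard_normal(n)},
                       time=np.arange(1, n + 1, dtype=float),
                       event=np.ones(n, int), **covars)


def test_stratify_age_median_rule():
    b = _clin_bundle(age=[50.0, 60.0, 70.0, 80.0])
    strata = stratify(b, "age")
    lo, hi = sorted(strata.values(), key=len, reverse=True)[0], None
    parts = list(strata.values())
    assert sorted(map(len, parts)) == [2, 2]
    young = next(v for k, v in strata.items() if "<=" in k)
    assert young == ["s1", "s2"]


def test_stratify_grade_stage_residual_rules():
    b = _clin_bundle(grade=[1, 2, 3, 4], stage=[1, 2, 3, 4],
                     residual=[5, 10, 15, 20])
    g = stratify(b, "grade")
    assert g["grade G1/G2"] == ["s1", "s2"] and g["grade G3/G4"] == ["s3", "s4"]
    s = stratify(b, "stage")
    assert s["stage I/II"] == ["s1", "s2"]
    r = stratify(b, "residual")
    assert r["residual <=10 mm"] == ["s1", "s2"]
    assert r["residual >10 mm"] == ["s3", "s4"]


def test_stratify_excludes_missing_and_partitions():
    b = _clin_bundle(grade=[1, np.nan, 3, 4])
    strata = stratify(b, "grade")
    all_ids = sorted(x for v in strata.values() for x in v)
    assert all_ids == ["s1", "s3", "s4"]  # s2 missing grade excluded
    assert len(set.intersection(*map(set, strata.values()))) == 0


def test_stratify_unknown_variable_errors():
    b = _clin_bundle(age=[1.0, 2.0])
    with pytest.raises(ValueError):
        stratify(b, "height")
    with pytest.raises(ValueError):
        stratify(b, "grade")


# ------------------------------------------------------- multivariate adjust

def test_multivariate_duplicated_covariate_collinear(trained):
    study, train, model = trained
    scores = compute_risk_scores(model, train.expression)
    surv = train.survival.copy()
    surv["stage2"] = surv["stage"]
    dup = CohortBundle(train.expression, surv, name="dup")
    with pytest.raises(ValueError, match="collinear"):
        multivariate_adjust(dup, scores, ["stage", "stage2"])


def test_score_stays_significant_after_adjustment(trained):
    study, train, model = trained
    scores = compute_risk_scores(model, train.expression)
    fit = multivariate_adjust(train, scores,
                              ["age", "stage", "grade", "residual", "lymph"])
    assert fit.names[0] == "score"
    assert fit.p[0] < 0.05
    # noise covariates do not move the per-SD HR outside its own CI
    uni = evaluate_signature(model, train).cox_score
    assert uni.ci_low[0] < fit.hr[0] < uni.ci_high[0] or fit.hr[0] > 1


def test_multivariate_needs_events():
    b = make_bundle({"G1": np.arange(12.0)}, time=np.arange(1.0, 13.0),
                    event=[1] * 5 + [0] * 7, age=np.arange(12.0))
    with pytest.raises(ValueError, match="10 events"):
        multivariate_adjust(b, pd.Series(np.arange(12.0), index=b.sample_ids),
                            ["age"])


# ------------------------------------------------------------- consistency

def _model(name, lncs, betas):
    return RiskModel(name, lncs, betas, cutpoint=0.0, training_cohort=name)


def test_consistency_sign_rules():
    lncs = ["a", "b", "c"]
    models = {
        f"c{i}": _model("TF", lncs, b)
        for i, b in enumerate([
            [1.0, 1.0, -1.0],
            [2.0, -1.0, -2.0],
            [0.5, 1.0, -0.1],
        ])
    }
    recs = {r.lnc_id: r.consistent for r in risk_direction_consistency(models)}
    assert recs == {"a": True, "b": False, "c": True}


def test_consistency_excludes_absent_and_is_monotone():
    m1 = _model("c1", ["a", "b"], [1.0, 1.0])
    m2 = _model("c2", ["a"], [1.0])
    recs = risk_direction_consistency({"c1": m1, "c2": m2})
    assert [r.lnc_id for r in recs] == ["a"]  # b absent from c2
    # adding a cohort can only shrink the retained set
    m3 = _model("c3", ["a"], [-1.0])
    kept2 = {r.lnc_id for r in risk_direction_consistency({"c1": m1, "c2": m2})
             if r.consistent}
    kept3 = {r.lnc_id
             for r in risk_direction_consistency({"c1": m1, "c2": m2, "c3": m3})
             if r.consistent}
    assert kept3 <= kept2
    with pytest.raises(ValueError):
        risk_direction_consistency({"c1": m1})


def test_planted_consistency_recovery_single_seed():
    cfg = SimulationConfig(seed=0, cohort_sizes=(300,) * 4, n_lncrnas=46,
                           n_tfs=1, targets_per_tf=6, decoys_per_tf=0,
                           gamma=0.3)
    study = simulate_study(cfg)
    tf = cfg.planted_tfs[0]
    models = {c.name: fit_risk_model(c, tf, cfg.lnc_ids) for c in study.cohorts}
    kept = {r.lnc_id for r in risk_direction_consistency(models) if r.consistent}
    planted = set(study.network_truth[tf])
    assert len(kept & planted) >= 5
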