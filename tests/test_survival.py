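"""Model fitting, curve prediction, importance ranking and KM bands."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import xenoeq as xq
from xenoeq.errors import (EstimationError, MissingCovariateError,
                           UnsupportedBackendError, XenoeqError)
from xenoeq.survival import VariableImportanceTable

from conftest import make_patient, patient_frame


def test_km_backend_tracks_exponential_truth():
    rng = np.random.default_rng(2)
    df = patient_frame([{} for _ in range(4000)])
    df["outcome_time"] = rng.exponential(1 / 0.3, size=len(df)).clip(1e-4)
    df["outcome_type"] = "death_or_delisting"
    m = xq.fit_model(df, "waitlist_death", backend="km", horizon=10.0)
    c = xq.predict_curve(m, df.iloc[0])
    t = c.times
    assert np.max(np.abs(c.probabilities - np.exp(-0.3 * t))) < 0.03


def test_cox_recovers_planted_diabetes_effect():
    cfg = xq.default_config(seed=21, n_patients=5000)
    m = xq.fit_model(xq.generate_registry(cfg).patients, "waitlist_death")
    truth = cfg.death_hazard_coefs["diabetes"]
    assert truth - 0.1 <= m.coefs["diabetes"] <= truth + 0.1


def test_zero_events_raise_estimation_error():
    df = patient_frame([{} for _ in range(60)])  # all censored
    with pytest.raises(EstimationError):
        xq.fit_model(df, "waitlist_death")


def test_null_coefficients_predict_the_baseline(death_model):
    null = dataclasses.replace(
        death_model, coefs={c: 0.0 for c in death_model.covariates})
    c = xq.predict_curve(null, make_patient(age_at_listing=75.0, cpra=99.9))
    assert np.allclose(c.probabilities, null.baseline_survival, atol=1e-12)


def test_positive_hazard_ratio_orders_curves_pointwise(death_model):
    assert death_model.coefs["diabetes"] > 0
    sick = xq.predict_curve(death_model, make_patient(diabetes=True))
    well = xq.predict_curve(death_model, make_patient(diabetes=False))
    assert np.all(sick.probabilities <= well.probabilities + 1e-12)


def test_predicted_curves_satisfy_invariants(models, active):
    # property over a spread of real patients and all three targets
    sample = active.iloc[::97]
    recipients = active[active["outcome_type"] == "transplant"].iloc[::41]
    for model, pats in ((models.waitlist_death, sample),
                        (models.time_to_transplant, sample),
                        (models.post_transplant_death, recipients)):
        S = model.predict_matrix(pats)
        assert np.allclose(S[:, 0], 1.0)
        assert np.all(S >= -1e-12) and np.all(S <= 1 + 1e-12)
        assert np.all(np.diff(S, axis=1) <= 1e-9)


def test_missing_covariate_is_named(death_model):
    with pytest.raises(MissingCovariateError, match="albumin"):
        xq.predict_curve(death_model,
                         make_patient().drop(labels=["albumin"]))


def test_rsf_predictions_are_seed_deterministic():
    b = xq.generate_registry(xq.default_config(seed=3, n_patients=800))
    kw = dict(backend="rsf", n_estimators=30, seed=5)
    m1 = xq.fit_model(b.patients, "waitlist_death", **kw)
    m2 = xq.fit_model(b.patients, "waitlist_death", **kw)
    p = b.patients.iloc[17]
    assert np.array_equal(xq.predict_curve(m1, p).probabilities,
                          xq.predict_curve(m2, p).probabilities)


def test_planted_signal_ranks_first_under_both_backends():
    # one covariate with log-HR 1.5, all others null: it must rank 1st
    cfg = xq.default_config(
        seed=13, n_patients=1500,
        death_hazard_coefs={"baseline": 0.15, "shape": 1.0, "age_c": 1.5},
        transplant_hazard_coefs={"baseline": 0.0},
        censor_rate=0.0)
    pats = xq.generate_registry(cfg).patients
    covs = ["age_c", "diabetes", "albumin_c", "bmi_c"]
    cox = xq.fit_model(pats, "waitlist_death", covariates=covs)
    assert xq.variable_importance(cox, pats).top(1) == ["age_c"]
    rsf = xq.fit_model(pats, "waitlist_death", backend="rsf",
                       covariates=covs, n_estimators=50, seed=1)
    vi = xq.variable_importance(rsf, pats.iloc[1000:], seed=1, n_repeats=5)
    assert vi.top(1) == ["age_c"]


def test_km_backend_has_no_importance(death_model, active):
    km = xq.fit_model(active, "waitlist_death", backend="km")
    with pytest.raises(UnsupportedBackendError):
        xq.variable_importance(km, active)


def _table(order):
    return VariableImportanceTable(
        backend="cox",
        entries={v: (1.0 / (i + 1), i + 1) for i, v in enumerate(order)})


def test_top_k_union_matches_published_style_lists():
    rsf = _table(["age", "diabetes", "waiting_time", "blood_type", "prev_tx"])
    cox = _table(["diabetes", "age", "prev_tx", "waiting_time", "blood_type"])
    assert xq.top_k_union(rsf, cox, 3) == {"age", "diabetes", "waiting_time",
                                           "prev_tx"}
    assert xq.top_k_union(rsf, rsf, 3) == {"age", "diabetes", "waiting_time"}
    disjoint = _table(["blood_type", "prev_tx", "age", "diabetes",
                       "waiting_time"])
    assert len(xq.top_k_union(_table(["waiting_time", "diabetes", "age",
                                      "prev_tx", "blood_type"]),
                              disjoint, 2)) == 4
    with pytest.raises(XenoeqError):
        xq.top_k_union(rsf, cox, 6)


def test_km_equals_brute_force_product_limit():
    # 10-record hand fixture with censoring; oracle: explicit product limit
    times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
    event = [1, 1, 0, 1, 1, 0, 1, 1, 1, 1]
    df = patient_frame([{"outcome_time": t,
                         "outcome_type": ("death_or_delisting" if e
                                          else "censored")}
                        for t, e in zip(times, event)])
    band = xq.km_with_band(df, "waitlist_death", min_events=1)
    surv, at_risk = 1.0, len(times)
    expected = {}
    for t in sorted(set(times)):
        d = sum(1 for tt, ee in zip(times, event) if tt == t and ee)
        c = sum(1 for tt, ee in zip(times, event) if tt == t and not ee)
        surv *= (1 - d / at_risk)
        at_risk -= d + c
        expected[t] = surv
    for t, s in expected.items():
        i = np.searchsorted(band.curve.times, t)
        assert band.curve.probabilities[i] == pytest.approx(s, abs=1e-9)


def test_km_band_suppressed_below_fifteen_events():
    df = patient_frame([{"outcome_time": float(i + 1),
                         "outcome_type": "death_or_delisting"}
                        for i in range(14)])
    band = xq.km_with_band(df, "waitlist_death")
    assert band.suppressed and band.curve is None and band.n_events == 14
    df15 = patient_frame([{"outcome_time": float(i + 1),
                           "outcome_type": "death_or_delisting"}
                          for i in range(15)])
    assert not xq.km_with_band(df15, "waitlist_death").suppressed


def test_incidence_band_brackets_one_minus_km(active):
    band = xq.km_with_band(active, "time_to_transplant", kind="incidence")
    inc = band.curve.cumulative_probability
    assert inc[0] == 0.0 and np.all(np.diff(inc) >= -1e-12)
    assert np.all(band.lower <= inc + 1e-9)
    assert np.all(band.upper >= inc - 1e-9)


def test_competing_risks_incidence_is_below_censoring_variant(active):
    aj = xq.cumulative_incidence(active, "transplant")
    km = xq.km_with_band(active, "time_to_transplant", kind="incidence")
    t = min(aj.horizon, km.curve.horizon)
    # treating deaths as censored overstates transplant incidence
    assert aj.at(t) <= km.curve.at(t) + 1e-9
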