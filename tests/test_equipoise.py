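"""Equipoise engine: the n + p * LE_relist comparison and its invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import xenoeq as xq
from xenoeq.equipoise import RelistEstimate
from xenoeq.errors import RelistEstimationError, XenoeqError
from xenoeq.incentives import ScenarioParams, le_after_relisting_batch

from conftest import patient_frame


def test_le_with_xeno_formula_and_bounds():
    assert xq.le_with_xeno(2.0, 0.5, 4.0) == pytest.approx(4.0)
    assert xq.le_with_xeno(1.5, 0.0, 99.0) == pytest.approx(1.5)  # p=0 -> n
    grid = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
    vals = [xq.le_with_xeno(n, 0.4, 6.0) for n in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))  # strict in n
    assert all(v >= n for v, n in zip(vals, grid))     # le_xeno >= n
    with pytest.raises(XenoeqError):
        xq.le_with_xeno(-1.0, 0.5, 4.0)
    with pytest.raises(XenoeqError):
        xq.le_with_xeno(1.0, 0.5, -4.0)


def test_le_with_xeno_is_linear_in_p_and_le_relist():
    # finite differences recover the slopes of the bilinear formula
    f = xq.le_with_xeno
    n = 2.0
    assert f(n, 0.6, 8.0) - f(n, 0.5, 8.0) == pytest.approx(0.1 * 8.0)
    assert f(n, 0.5, 9.0) - f(n, 0.5, 8.0) == pytest.approx(0.5 * 1.0)


def test_relist_probability_boundaries():
    rows = [{"graft_failure": True, "relisted": True} for _ in range(20)]
    est = xq.estimate_relist_probability(patient_frame(rows))
    assert est.probability == 1.0 and est.n_events == 20
    rows = [{"graft_failure": True, "relisted": False} for _ in range(20)]
    assert xq.estimate_relist_probability(patient_frame(rows)).probability == 0.0
    with pytest.raises(RelistEstimationError, match="parent cohort"):
        xq.estimate_relist_probability(
            patient_frame([{"graft_failure": False}]))


def test_cohort_relist_estimate_matches_logistic_truth():
    # ground truth intercept -0.5 and no covariate effects: the cohort-level
    # empirical fraction must sit near expit(-0.5)
    cfg = xq.default_config(
        seed=31, n_patients=20_000,
        relist_logit_coefs={"intercept": -0.5},
        graft_failure_prob=0.9)
    b = xq.generate_registry(cfg)
    est = xq.estimate_relist_probability(b.patients)
    assert est.probability == pytest.approx(expit(-0.5), abs=0.02)


def test_individual_relist_estimates_track_covariates(bundle):
    pats = bundle.patients
    est = xq.estimate_relist_probability(pats, level="individual",
                                         patients=pats)
    p = np.asarray(est.probability)
    assert p.shape == (len(pats),)
    assert ((p >= 0) & (p <= 1)).all()
    # ground truth gives diabetics lower relisting odds
    assert p[pats["diabetes"]].mean() < p[~pats["diabetes"]].mean()


def test_identify_viable_rejects_inactive_patients(bundle, models):
    with pytest.raises(XenoeqError, match="inactive"):
        xq.identify_viable(bundle.patients, models, xq.XenoAssumptions())


def test_viable_flags_match_brute_force_comparison(active, models, bundle):
    pats = active.iloc[:300].reset_index(drop=True)
    assumptions = xq.XenoAssumptions(n_grid=(1.0, 2.0, 4.0))
    relist = xq.estimate_relist_probability(active)
    res = xq.identify_viable(pats, models, assumptions, relist=relist,
                             donors=bundle.donors)
    # independent recount: recompute both LE numbers outside the engine and
    # compare them per patient per n
    le_sq = xq.status_quo_le(pats, models.waitlist_death)
    le_relist = le_after_relisting_batch(pats, ScenarioParams(), models,
                                         donors=bundle.donors)
    for n in assumptions.n_grid:
        sub = res[res["n"] == n].set_index("patient_id")
        expect = (n + relist.probability * le_relist) > le_sq
        assert np.array_equal(sub["viable"].to_numpy(), expect)
        assert np.allclose(sub["le_status_quo"].to_numpy(), le_sq)
    # a tie is non-viable: viable is a strict inequality
    assert not (res["le_xeno"] == res["le_status_quo"]).any() or \
        not res.loc[res["le_xeno"] == res["le_status_quo"], "viable"].any()


def test_viable_sets_are_nested_in_n(active, models, bundle):
    pats = active.iloc[:400].reset_index(drop=True)
    res = xq.identify_viable(pats, models, xq.XenoAssumptions(),
                             donors=bundle.donors)
    grid = sorted(res["n"].unique())
    sets = {n: set(res[(res["n"] == n) & res["viable"]]["patient_id"])
            for n in grid}
    for a, b in zip(grid, grid[1:]):
        assert sets[a] <= sets[b]


def test_full_relisting_at_status_quo_makes_everyone_viable(active, models):
    # p_relist = 1 and le_relist = le_status_quo give le_xeno = n + le_sq
    pats = active.iloc[:50].reset_index(drop=True)
    le_sq = xq.status_quo_le(pats, models.waitlist_death)
    for n in (0.5, 2.0):
        assert np.all(n + 1.0 * le_sq > le_sq)


def test_sensitivity_table_tallies_and_monotonicity(active, models, bundle):
    pats = active.iloc[:400].reset_index(drop=True)
    assumptions = xq.XenoAssumptions()
    res = xq.identify_viable(pats, models, assumptions, donors=bundle.donors)
    table = xq.sensitivity_table(res, expected_grid=assumptions.n_grid)
    assert list(table["n"]) == sorted(table["n"])
    for row in table.itertuples():
        direct = res[(res["n"] == row.n)]["viable"]
        assert row.count_viable == int(direct.sum())
        assert row.fraction_viable == pytest.approx(direct.mean())
    # base scenario: le_relist does not depend on n => fractions non-decreasing
    assert (np.diff(table["fraction_viable"]) >= -1e-12).all()
    with pytest.raises(XenoeqError, match="missing n"):
        xq.sensitivity_table(res, expected_grid=(1.0, 2.5))


def test_all_viable_gives_unit_fractions():
    res = pd.DataFrame({"patient_id": [0, 1] * 2, "n": [1.0, 1.0, 2.0, 2.0],
                        "le_status_quo": 1.0, "le_xeno": 9.0, "viable": True})
    table = xq.sensitivity_table(res)
    assert (table["fraction_viable"] == 1.0).all()


def test_relist_estimate_validates_probability():
    with pytest.raises(XenoeqError):
        RelistEstimate(probability=1.2, level="cohort", n_events=5)
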