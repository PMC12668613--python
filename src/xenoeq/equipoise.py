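"""Equipoise comparison: life expectancy with vs. without a xenotransplant.

For each active waitlisted patient the engine compares

* ``le_status_quo`` — the restricted mean survival time of the patient's
  waitlist death-or-delisting curve, conditional on the waiting time already
  elapsed, and
* ``le_xeno`` — ``n + p_relist * le_relist``: the assumed xenograft survival
  ``n`` plus the probability of relisting after xenograft failure times the
  life expectancy after rejoining the waitlist (from the scenario engine).

A patient is *viable* (reaches clinical equipoise) when ``le_xeno`` strictly
exceeds ``le_status_quo``; ties are non-viable.  Because the xenograft
survival ``n`` is unknown, everything is swept over a sensitivity grid
(0.5, 1, 1.5, 2, 3, 4, 5 years by default).  The relisting probability is
proxied by relisting after *allograft* failure, at cohort level (empirical
fraction) or individual level (logistic model); CPRA is assumed unchanged
after xenograft failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry as reg
from .curves import condition_matrix
from .errors import RelistEstimationError, XenoeqError
from .incentives import (ModelSet, ScenarioParams, le_after_relisting_batch)
from .survival import FittedSurvivalModel

DEFAULT_N_GRID = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)


@dataclass
class XenoAssumptions:
    """Assumed xenograft survival grid and related knobs."""

    n_grid: tuple = DEFAULT_N_GRID
    q: float = 75.0
    cpra_policy: str = "fixed"  # CPRA unchanged after xenograft failure

    def __post_init__(self):
        if any(n <= 0 for n in self.n_grid):
            raise XenoeqError("all n values must be positive")
        self.n_grid = tuple(sorted(float(n) for n in self.n_grid))
        if not (0.0 < self.q <= 100.0):
            raise XenoeqError("q must lie in (0, 100]")


@dataclass(frozen=True)
class RelistEstimate:
    """Probability of relisting after graft failure, with provenance."""

    probability: float | np.ndarray
    level: str  # "individual" or "cohort"
    n_events: int

    def __post_init__(self):
        p = np.asarray(self.probability, float)
        if np.any(p < 0) or np.any(p > 1):
            raise XenoeqError("relist probability must lie in [0, 1]")


def estimate_relist_probability(records: pd.DataFrame,
                                level: str = "cohort",
                                cohort_mask=None,
                                patients: pd.DataFrame = None,
                                covariates=("diabetes", "age_c"),
                                ) -> RelistEstimate:
    """Estimate the relisting-after-graft-failure probability.

    ``cohort`` level: the empirical fraction relisted among graft failures
    (optionally within ``cohort_mask``).  ``individual`` level: a logistic
    model on the failure population's design columns, evaluated for
    ``patients`` (defaults to ``records``).  Raises
    :class:`RelistEstimationError` when the stratum has no graft failures
    (fall back to the parent cohort).
    """
    failures = records[records["graft_failure"].astype(bool)]
    if cohort_mask is not None:
        mask = pd.Series(np.asarray(cohort_mask, bool), index=records.index)
        failures = failures[mask.loc[failures.index]]
    n_events = len(failures)
    if n_events == 0:
        raise RelistEstimationError(
            "no graft failures in this stratum; fall back to the parent "
            "cohort estimate")
    if level == "cohort":
        return RelistEstimate(float(failures["relisted"].mean()),
                              "cohort", n_events)
    if level != "individual":
        raise XenoeqError(f"unknown relist level {level!r}")
    from sklearn.linear_model import LogisticRegression
    cols = list(covariates)
    Xf = reg.design_matrix(failures)[cols].to_numpy(float)
    y = failures["relisted"].astype(int).to_numpy()
    if y.min() == y.max():  # degenerate: every/no failure relisted
        return RelistEstimate(
            np.full(len(patients if patients is not None else records),
                    float(y[0])), "individual", n_events)
    clf = LogisticRegression(C=1e6, max_iter=1000)
    clf.fit(Xf, y)
    target = patients if patients is not None else records
    Xt = reg.design_matrix(target)[cols].to_numpy(float)
    return RelistEstimate(clf.predict_proba(Xt)[:, 1], "individual", n_events)


def le_with_xeno(n: float, relist: RelistEstimate | float,
                 le_relist: float) -> float:
    """n years of xenograft survival plus p_relist times the life
    expectancy after rejoining the waitlist."""
    p = relist.probability if isinstance(relist, RelistEstimate) else relist
    p = float(p)
    if n <= 0:
        raise XenoeqError("xenograft survival n must be positive")
    if le_relist < 0 or p < 0 or p > 1:
        raise XenoeqError("invalid relist probability or life expectancy")
    return float(n + p * le_relist)


def status_quo_le(patients: pd.DataFrame,
                  death_model: FittedSurvivalModel) -> np.ndarray:
    """Per-patient conditional life expectancy without a xenotransplant.

    The waitlist death-or-delisting curve is predicted from listing,
    conditioned on the waiting time already elapsed (snapped to the monthly
    grid) and integrated over the model horizon, with the tail carried
    forward at its last value.
    """
    grid = death_model.grid
    S = death_model.predict_matrix(patients)
    step = grid[1] - grid[0]
    elapsed = patients["waiting_time_elapsed"].to_numpy(float)
    offsets = np.clip(np.rint(elapsed / step).astype(int), 0, len(grid) - 1)
    S_cond = condition_matrix(S, offsets)
    return np.trapezoid(S_cond, grid, axis=1)


def identify_viable(patients: pd.DataFrame, models: ModelSet,
                    assumptions: XenoAssumptions,
                    scenario: ScenarioParams = None,
                    relist: RelistEstimate = None,
                    donors: pd.DataFrame = None) -> pd.DataFrame:
    """One equipoise comparison per active patient per n on the grid.

    Returns a frame with columns ``patient_id, n, le_status_quo, le_xeno,
    viable``.  Raises when inactive patients are present: the analysis
    population excludes them, and filtering is the caller's responsibility.
    """
    if not patients["active"].astype(bool).all():
        raise XenoeqError(
            "inactive patients present; filter to active patients first")
    scenario = scenario or ScenarioParams(scenario="base")
    if relist is None:
        relist = estimate_relist_probability(patients, level="cohort")
    p = np.broadcast_to(np.asarray(relist.probability, float),
                        (len(patients),))

    le_sq = status_quo_le(patients, models.waitlist_death)
    static = scenario.scenario != "inactive_accrual"
    if static:
        le_relist = le_after_relisting_batch(patients, scenario, models,
                                             donors=donors)
    frames = []
    for n in assumptions.n_grid:
        if not static:
            le_relist = le_after_relisting_batch(patients, scenario, models,
                                                 donors=donors, n=n)
        le_x = n + p * le_relist
        frames.append(pd.DataFrame({
            "patient_id": patients["patient_id"].values,
            "n": float(n),
            "le_status_quo": le_sq,
            "le_xeno": le_x,
            "viable": le_x > le_sq,
        }))
    return pd.concat(frames, ignore_index=True)


def sensitivity_table(results: pd.DataFrame, assignments: pd.DataFrame = None,
                      expected_grid=None) -> pd.DataFrame:
    """Fraction and count of viable patients per n (and per cohort).

    ``assignments`` is an optional (patient_id, cohort_id) table; without it
    the whole population is one group.  Raises when an expected n is absent
    from the results.
    """
    if expected_grid is not None:
        missing = set(float(n) for n in expected_grid) - \
            set(results["n"].unique())
        if missing:
            raise XenoeqError(f"results are missing n values: {sorted(missing)}")
    df = results
    keys = ["n"]
    if assignments is not None:
        df = assignments.merge(results, on="patient_id")
        keys = ["cohort_id", "n"]
    out = (df.groupby(keys)["viable"]
             .agg(fraction_viable="mean", count_viable="sum",
                  n_patients="size")
             .reset_index())
    out["count_viable"] = out["count_viable"].astype(int)
    return out.sort_values(keys, ignore_index=True)
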