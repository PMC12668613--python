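"""Life expectancy after relisting under counterfactual allocation scenarios.

When a xenograft fails after ``n`` years, the patient may rejoin the
allotransplant waitlist.  Their remaining life expectancy is computed with a
discrete-time two-phase (semi-Markov) recursion on the monthly grid: while
waiting, the patient faces the waitlist death-or-delisting hazard and the
time-to-transplant hazard; upon transplant at time t they collect the
post-transplant life expectancy of a patient of their (aged) covariates
matched to a donor of mean quality, truncated at the remaining horizon:

    LE = integral S_death(t) * S_no-tx(t) dt
       + sum_t S_death(t) * dF_tx(t) * LE_post(t)

Four scenarios modify the transplant process:

* ``base`` — relisting with waiting time reset to zero;
* ``inactive_accrual`` — the patient stayed on the list inactive during the
  xenograft's life, so the time-to-transplant curve is conditioned on a
  waiting-time credit of (elapsed wait + n) years;
* ``living_donor_priority`` — priority points equivalent to a former living
  donor, modelled as a proportional multiplier (> 1) on the transplant
  hazard;
* ``highest_priority`` — immediate transplant with an ideal organ: the
  blood-compatible donor pool is scored by post-transplant life expectancy
  and the q-th percentile (nearest rank, q = 75 by default) is returned.

Covariates other than age are frozen at listing; the patient's age at
relisting is age at listing plus elapsed waiting time (aging during the
xenograft itself is ignored so the base scenario is independent of n), and
age continues to advance with time waited in the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from . import registry as reg
from .curves import MONTH, condition_matrix, time_grid
from .errors import (EmptyDonorPoolError, UnsupportedBackendError,
                     XenoeqError)
from .survival import FittedSurvivalModel

SCENARIOS = ("base", "inactive_accrual", "living_donor_priority",
             "highest_priority")

#: donor blood type -> recipient blood types it can serve
ABO_COMPATIBLE = {
    "O": {"O", "A", "B", "AB"},
    "A": {"A", "AB"},
    "B": {"B", "AB"},
    "AB": {"AB"},
}


@dataclass
class ScenarioParams:
    """One incentive scenario and its knobs."""

    scenario: str = "base"
    q: float = 75.0
    priority_multiplier: float = 5.0
    time_step: float = MONTH
    horizon: float = 25.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise XenoeqError(
                f"unknown scenario {self.scenario!r}; expected {SCENARIOS}")
        if self.priority_multiplier < 1.0:
            raise XenoeqError("priority_multiplier must be >= 1")
        if not (0.0 < self.q <= 100.0):
            raise XenoeqError("q must lie in (0, 100]")


@dataclass
class ModelSet:
    """The three fitted models the scenario engine needs."""

    waitlist_death: FittedSurvivalModel
    time_to_transplant: FittedSurvivalModel
    post_transplant_death: FittedSurvivalModel


def semi_markov_le(times: np.ndarray, s_wait: np.ndarray,
                   g_notx: np.ndarray, le_post: np.ndarray) -> np.ndarray:
    """Two-phase life expectancy from component arrays on a common grid.

    ``s_wait`` is P(not dead at t) while waiting, ``g_notx`` is P(not yet
    transplanted at t) (both with independent latent times, so P(alive and
    waiting) is their product) and ``le_post[..., j]`` is the remaining
    post-transplant life expectancy if transplanted at ``times[j]``.  All
    arrays share the last axis with ``times``; leading axes broadcast over
    patients.  Waiting person-time and post-transplant person-time are
    counted once each (midpoint rule for within-interval transplants).
    """
    s_wait = np.atleast_2d(s_wait)
    g_notx = np.atleast_2d(g_notx)
    le_post = np.atleast_2d(le_post)
    waiting = np.trapezoid(s_wait * g_notx, times, axis=-1)
    df = g_notx[..., :-1] - g_notx[..., 1:]          # P(tx in interval)
    s_mid = 0.5 * (s_wait[..., :-1] + s_wait[..., 1:])
    le_mid = 0.5 * (le_post[..., :-1] + le_post[..., 1:])
    post = np.sum(df * s_mid * le_mid, axis=-1)
    out = waiting + post
    return out[0] if out.shape[0] == 1 and out.ndim == 1 else out


def _records_at_relisting(patients: pd.DataFrame) -> pd.DataFrame:
    """Patient records with age advanced by the elapsed waiting time."""
    rec = patients.copy()
    rec["age_at_listing"] = (rec["age_at_listing"]
                             + rec["waiting_time_elapsed"])
    return rec


class _PostTxTable:
    """Horizon-truncated post-transplant LE as a function of the Cox linear
    predictor, tabulated once and interpolated.

    C[g, j] = integral_0^{t_j} S0(u)^exp(lp_g) du on a dense lp grid; the
    remaining LE for a transplant at t_j is C[., T-j].
    """

    def __init__(self, model: FittedSurvivalModel, grid: np.ndarray,
                 lp_lo: float, lp_hi: float, n_points: int = 200):
        if model.backend != "cox":
            raise UnsupportedBackendError(
                "the scenario engine requires a cox post-transplant model")
        self.model = model
        self.grid = grid
        pad = 0.25
        self.lp_grid = np.linspace(lp_lo - pad, lp_hi + pad, n_points)
        s0 = np.clip(model.baseline_survival, 1e-300, 1.0)
        S = s0[None, :] ** np.exp(self.lp_grid)[:, None]
        self.C = cumulative_trapezoid(S, grid, axis=1, initial=0.0)

    def le_at(self, lp: np.ndarray, remaining_index: int) -> np.ndarray:
        return np.interp(lp, self.lp_grid, self.C[:, remaining_index])


def _post_lp_base(patients: pd.DataFrame, post_model: FittedSurvivalModel,
                  donor_quality) -> tuple[np.ndarray, float]:
    """Centred post-transplant linear predictor at relisting (t=0) with the
    given donor quality, plus the age slope per year of extra waiting."""
    rec = _records_at_relisting(patients).copy()
    rec["donor_quality"] = donor_quality
    X = reg.design_matrix(rec)[list(post_model.covariates)]
    lp0 = post_model.linear_predictor(X)
    beta_age = post_model.coefs.get("age_c", 0.0) / 10.0  # per year of age
    return lp0, beta_age


def _le_post_matrix(patients, post_model, grid, mean_quality):
    """(n_patients, T+1) remaining post-tx LE if transplanted at each grid
    time, with mean donor quality and age advancing along the wait."""
    lp0, beta_age = _post_lp_base(patients, post_model, mean_quality)
    lp_span = lp0[:, None] + beta_age * grid[None, :]
    table = _PostTxTable(post_model, grid, float(lp_span.min()),
                         float(lp_span.max()))
    T = len(grid) - 1
    out = np.empty((len(lp0), T + 1))
    for j in range(T + 1):
        out[:, j] = table.le_at(lp0 + beta_age * grid[j], T - j)
    return out


def highest_priority_le(patient, donors: pd.DataFrame,
                        post_model: FittedSurvivalModel,
                        q: float = 75.0) -> float:
    """q-th percentile (nearest rank) of post-transplant life expectancy
    over the patient's blood-compatible donor pool, assuming immediate
    transplant at relisting."""
    row = patient if isinstance(patient, pd.Series) else pd.Series(patient)
    les = _highest_priority_le_batch(pd.DataFrame([row]), donors, post_model, q)
    return float(les[0])


def _highest_priority_le_batch(patients, donors, post_model, q):
    grid = post_model.grid
    T = len(grid) - 1
    qual = donors["quality"].to_numpy(float)
    dbt = donors["blood_type"].to_numpy()
    beta_dq = post_model.coefs.get("donor_quality", 0.0)
    lp0, _ = _post_lp_base(patients, post_model, 0.0)
    lo = lp0.min() + min(beta_dq * qual.min(), beta_dq * qual.max())
    hi = lp0.max() + max(beta_dq * qual.min(), beta_dq * qual.max())
    table = _PostTxTable(post_model, grid, float(lo), float(hi))
    out = np.empty(len(patients))
    rbt = patients["blood_type"].to_numpy()
    for i in range(len(patients)):
        mask = np.fromiter((rbt[i] in ABO_COMPATIBLE[b] for b in dbt),
                           dtype=bool, count=len(dbt))
        if not mask.any():
            raise EmptyDonorPoolError(
                f"no blood-compatible donor for recipient type {rbt[i]}")
        les = table.le_at(lp0[i] + beta_dq * qual[mask], T)
        les.sort()
        rank = int(np.ceil(q / 100.0 * les.size)) - 1  # nearest rank
        out[i] = les[rank]
    return out


def le_after_relisting_batch(patients: pd.DataFrame, params: ScenarioParams,
                             models: ModelSet, donors: pd.DataFrame = None,
                             n: float = 0.0) -> np.ndarray:
    """Per-patient life expectancy after rejoining the waitlist.

    ``n`` (the xenograft survival) only matters for ``inactive_accrual``,
    where it adds to the waiting-time credit; ``highest_priority`` requires
    the donor pool.
    """
    death = models.waitlist_death
    tx = models.time_to_transplant
    grid = death.grid
    if len(grid) != len(tx.grid) or death.horizon != tx.horizon:
        raise XenoeqError("death and transplant models use mismatched grids")

    if params.scenario == "highest_priority":
        if donors is None or len(donors) == 0:
            raise EmptyDonorPoolError(
                "highest_priority scenario needs a donor pool")
        return _highest_priority_le_batch(patients, donors,
                                          models.post_transplant_death,
                                          params.q)

    rec = _records_at_relisting(patients)
    S_d = death.predict_matrix(rec)
    G = tx.predict_matrix(rec)  # P(no transplant by t), waiting reset to 0

    if params.scenario == "inactive_accrual":
        credit = patients["waiting_time_elapsed"].to_numpy(float) + n
        step = grid[1] - grid[0]
        offsets = np.clip(np.rint(credit / step).astype(int), 0, len(grid) - 1)
        G = condition_matrix(G, offsets)
    elif params.scenario == "living_donor_priority":
        if params.priority_multiplier != 1.0:
            G = np.clip(G, 1e-300, 1.0) ** params.priority_multiplier

    mean_quality = (float(donors["quality"].mean())
                    if donors is not None and len(donors) else 0.6)
    le_post = _le_post_matrix(patients, models.post_transplant_death, grid,
                              mean_quality)
    return np.asarray(semi_markov_le(grid, S_d, G, le_post), float).reshape(-1)


def le_after_relisting(patient, params: ScenarioParams, models: ModelSet,
                       donors: pd.DataFrame = None, n: float = 0.0) -> float:
    """Single-patient convenience wrapper around the batch recursion."""
    row = patient if isinstance(patient, pd.Series) else pd.Series(patient)
    return float(le_after_relisting_batch(pd.DataFrame([row]), params, models,
                                          donors=donors, n=n)[0])


def incentivized_fractions(patients: pd.DataFrame,
                           cohort_assignments: pd.DataFrame,
                           scenarios, assumptions, models: ModelSet,
                           donors: pd.DataFrame,
                           relist_probability,
                           suppression_size: int = 15) -> pd.DataFrame:
    """Fraction of each cohort reaching equipoise per (scenario, n).

    Returns one row per (cohort_id, scenario, n) with the fraction
    incentivized, the delta in percentage points versus the base scenario,
    and a suppression flag for cohorts below ``suppression_size``.  The base
    scenario is always computed so deltas are well defined.
    """
    from .equipoise import status_quo_le  # local import avoids a cycle

    scen_list = list(scenarios)
    if not any(s.scenario == "base" for s in scen_list):
        scen_list = [ScenarioParams(scenario="base")] + scen_list

    le_sq = status_quo_le(patients, models.waitlist_death)
    p = np.broadcast_to(np.asarray(relist_probability, float),
                        (len(patients),))

    rows = []
    frac_base = {}
    for params in scen_list:
        static = params.scenario != "inactive_accrual"
        if static:
            le_relist = le_after_relisting_batch(patients, params, models,
                                                 donors=donors)
        for n in assumptions.n_grid:
            if not static:
                le_relist = le_after_relisting_batch(patients, params, models,
                                                     donors=donors, n=n)
            le_xeno = n + p * le_relist
            viable = le_xeno > le_sq
            vdf = pd.DataFrame({"patient_id": patients["patient_id"].values,
                                "viable": viable})
            merged = cohort_assignments.merge(vdf, on="patient_id")
            for cid, grp in merged.groupby("cohort_id"):
                frac = float(grp["viable"].mean())
                if params.scenario == "base":
                    frac_base[(cid, n)] = frac
                rows.append({
                    "cohort_id": int(cid), "scenario": params.scenario,
                    "n": float(n), "fraction_incentivized": frac,
                    "n_patients": int(len(grp)),
                    "suppressed": len(grp) < suppression_size,
                })
    out = pd.DataFrame(rows)
    out["delta_vs_base"] = [
        100.0 * (r.fraction_incentivized - frac_base.get((r.cohort_id, r.n),
                                                         np.nan))
        for r in out.itertuples()]
    return out.sort_values(["cohort_id", "scenario", "n"],
                           ignore_index=True)
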