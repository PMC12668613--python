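"""High-need patient cohorts and the center aggressiveness score.

Eleven overlapping cohorts combine the covariates that matter most for both
waitlist survival and transplant access: diabetes, blood type B/O (the
slow-to-match groups), the 50-64 / 65+ age bands used in national
reporting, elapsed waiting time (< 3 vs >= 3 years), the listing center's
aggressiveness tertile, and very high sensitization (CPRA >= 99.5).  All
conditions within a cohort are conjunctive, age intervals are half-open
[lo, hi), and cohorts overlap by construction (e.g. cohort 3 is cohort 1
restricted to >= 3 years waited).

Center *aggressiveness* is the product of two rates computed from the
marginal-organ offer log: the acceptance rate (marginal organs accepted /
marginal organs offered to the center's patients) and the offer-seen rate
(mean over the center's patients of the fraction of their marginal offers
that passed the opt-in screen).  Centers are classified into top / middle /
bottom tertiles by score, ties broken by center id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import XenoeqError
from .survival import km_with_band

TERTILES = ("top", "middle", "bottom")


@dataclass(frozen=True)
class CohortDefinition:
    """Conjunctive membership predicate for one cohort."""

    cohort_id: int
    diabetes_required: bool | None = None
    blood_types: frozenset | None = None
    age_interval: tuple | None = None        # [lo, hi), hi may be inf
    waiting_time_condition: str | None = None  # ">=3y" | "<3y"
    center_tertile: str | None = None          # "top" | "bottom"
    cpra_min: float | None = None

    def matches(self, patient, tertile_of_center=None) -> bool:
        if self.diabetes_required and not bool(patient["diabetes"]):
            return False
        if self.blood_types is not None and \
                patient["blood_type"] not in self.blood_types:
            return False
        if self.age_interval is not None:
            lo, hi = self.age_interval
            if not (lo <= patient["age_at_listing"] < hi):
                return False
        if self.waiting_time_condition == ">=3y" and \
                patient["waiting_time_elapsed"] < 3.0:
            return False
        if self.waiting_time_condition == "<3y" and \
                patient["waiting_time_elapsed"] >= 3.0:
            return False
        if self.center_tertile is not None:
            if tertile_of_center is None:
                raise XenoeqError(
                    f"cohort {self.cohort_id} needs center tertiles")
            if tertile_of_center != self.center_tertile:
                return False
        if self.cpra_min is not None and patient["cpra"] < self.cpra_min:
            return False
        return True


_BO = frozenset({"B", "O"})
_MID = (50.0, 64.0)
_OLD = (65.0, math.inf)

#: The eleven study cohorts (intervals half-open as printed).
DEFAULT_COHORTS = (
    CohortDefinition(1, True, _BO, _MID),
    CohortDefinition(2, True, _BO, _OLD),
    CohortDefinition(3, True, _BO, _MID, ">=3y"),
    CohortDefinition(4, True, _BO, _OLD, ">=3y"),
    CohortDefinition(5, True, _BO, _MID, "<3y"),
    CohortDefinition(6, True, _BO, _OLD, "<3y"),
    CohortDefinition(7, True, _BO, _MID, None, "bottom"),
    CohortDefinition(8, True, _BO, _OLD, None, "bottom"),
    CohortDefinition(9, True, _BO, _MID, None, "top"),
    CohortDefinition(10, True, _BO, _OLD, None, "top"),
    CohortDefinition(11, cpra_min=99.5),
)


def assign_cohorts(patient, aggressiveness_map: dict = None,
                   cohorts=DEFAULT_COHORTS) -> set:
    """All cohort ids whose predicate the patient satisfies (possibly empty).

    ``aggressiveness_map`` maps center_id -> tertile; required when any
    cohort conditions on the center tertile and raised about when absent.
    """
    tert = None
    if aggressiveness_map is not None:
        cid = patient["center_id"]
        if cid not in aggressiveness_map and any(
                c.center_tertile for c in cohorts):
            raise XenoeqError(f"unknown center {cid} for tertile lookup")
        tert = aggressiveness_map.get(cid)
    out = set()
    for c in cohorts:
        if c.center_tertile is not None and aggressiveness_map is None:
            raise XenoeqError(f"cohort {c.cohort_id} needs center tertiles")
        if c.matches(patient, tert):
            out.add(c.cohort_id)
    return out


def assign_cohorts_frame(patients: pd.DataFrame,
                         aggressiveness_map: dict = None,
                         cohorts=DEFAULT_COHORTS) -> pd.DataFrame:
    """Long (patient_id, cohort_id) assignment table for a patient frame."""
    rows = []
    for _, p in patients.iterrows():
        for cid in sorted(assign_cohorts(p, aggressiveness_map, cohorts)):
            rows.append((p["patient_id"], cid))
    return pd.DataFrame(rows, columns=["patient_id", "cohort_id"])


def acceptance_rate(offers: pd.DataFrame, center_id) -> float:
    """Marginal organs accepted / marginal organs offered for one center.

    NaN (undefined) when the center received no marginal offers.
    """
    m = offers[(offers["center_id"] == center_id) & offers["marginal"]]
    if len(m) == 0:
        return float("nan")
    return float(m["accepted"].mean())


def offer_seen_rate(offers: pd.DataFrame, center_id) -> float:
    """Mean over the center's patients of their seen/offered marginal
    fraction; NaN when the center has no patients with marginal offers."""
    m = offers[(offers["center_id"] == center_id) & offers["marginal"]]
    if len(m) == 0:
        return float("nan")
    return float(m.groupby("patient_id")["seen"].mean().mean())


@dataclass(frozen=True)
class AggressivenessScore:
    center_id: int
    acceptance_rate: float
    offer_seen_rate: float
    score: float
    tertile: str | None  # None when undefined (excluded from tertiles)

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.acceptance_rate)
                    or np.isnan(self.offer_seen_rate))


def aggressiveness(offers: pd.DataFrame, center_ids=None) -> pd.DataFrame:
    """Aggressiveness score and tertile for every center.

    score = acceptance_rate * offer_seen_rate (so the score is bounded by
    both components).  Centers with an undefined component are flagged and
    excluded from the tertile ranking.  Tertiles take the floor(n/3)
    highest-scoring centers as "top" and the floor(n/3) lowest as "bottom";
    ties are broken by center id for determinism.
    """
    if center_ids is None:
        center_ids = sorted(offers["center_id"].unique())
    rows = []
    for cid in center_ids:
        a = acceptance_rate(offers, cid)
        s = offer_seen_rate(offers, cid)
        rows.append({"center_id": cid, "acceptance_rate": a,
                     "offer_seen_rate": s, "score": a * s})
    df = pd.DataFrame(rows)
    df["tertile"] = None
    defined = df[df["score"].notna()]
    ranked = defined.sort_values(["score", "center_id"],
                                 ascending=[False, True])
    k = len(ranked) // 3
    if k > 0:
        df.loc[ranked.index[:k], "tertile"] = "top"
        df.loc[ranked.index[-k:], "tertile"] = "bottom"
        mid = ranked.index[k:-k] if len(ranked) > 2 * k else []
        df.loc[mid, "tertile"] = "middle"
    return df


def tertile_map(scores: pd.DataFrame) -> dict:
    """center_id -> tertile dict from an aggressiveness table."""
    return {r.center_id: r.tertile for r in scores.itertuples()
            if r.tertile is not None}


def cohort_report(members: pd.DataFrame, sensitivity: pd.DataFrame = None,
                  min_events: int = 15) -> dict:
    """Cohort-level curves with 95% bands plus size and sensitivity rows.

    ``members`` is the cohort's patient subset; raises on an empty cohort.
    Survival uses the death-or-delisting target; time-to-transplant is
    one-minus-KM of the transplant event.  Either curve is suppressed when
    its event count falls below ``min_events``.
    """
    if len(members) == 0:
        raise XenoeqError("empty cohort")
    return {
        "size": int(len(members)),
        "survival": km_with_band(members, "waitlist_death", "survival",
                                 min_events),
        "time_to_transplant": km_with_band(members, "time_to_transplant",
                                           "incidence", min_events),
        "sensitivity": sensitivity,
    }
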