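"""Hit rate and capture rate of short-life-expectancy identification.

Given an analysis period tau, a patient is *identified* when the model
predicts a life expectancy of tau years or fewer (inclusive), and is a
*case* when death-or-delisting occurs within tau years.  The hit rate is
the fraction of identified patients who are cases (precision) and the
capture rate the fraction of cases who were identified (recall).

Patients censored before tau without an observed death are excluded from
both denominators (the configured censoring policy — their tau-year status
is unknown).  Patients transplanted before tau are retained as non-cases:
they left the waitlist alive.  A report whose number of correctly
identified patients falls below ``min_correct`` (15 by default) is flagged
as suppressed, mirroring small-cell reporting rules; undefined rates (empty
denominators) are flagged, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import XenoeqError


@dataclass(frozen=True)
class MetricsConfig:
    tau: float
    min_correct: int = 15
    censor_policy: str = "exclude_censored_before_tau"

    def __post_init__(self):
        if self.tau <= 0:
            raise XenoeqError("tau must be positive")
        if self.min_correct < 0:
            raise XenoeqError("min_correct must be non-negative")
        if self.censor_policy != "exclude_censored_before_tau":
            raise XenoeqError(
                f"unknown censor policy {self.censor_policy!r}")


@dataclass(frozen=True)
class MetricsReport:
    n_identified: int
    n_died_within_tau: int
    n_correct: int
    hit_rate: float | None       # None when no patient was identified
    capture_rate: float | None   # None when no patient died within tau
    suppressed: bool
    tau: float
    n_evaluated: int
    censor_policy: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tau", "n_evaluated", "n_identified", "n_died_within_tau",
            "n_correct", "hit_rate", "capture_rate", "suppressed",
            "censor_policy")}


def _eligible(outcomes: pd.DataFrame, tau: float) -> pd.DataFrame:
    censored_early = (outcomes["outcome_type"] == "censored") & \
        (outcomes["outcome_time"] < tau)
    return outcomes[~censored_early]


def evaluate(predicted_le: pd.Series, outcomes: pd.DataFrame,
             config: MetricsConfig) -> MetricsReport:
    """Hit/capture report for predictions against observed outcomes.

    ``predicted_le`` is indexed by patient_id; ``outcomes`` has columns
    patient_id, outcome_type, outcome_time.  Both must cover the same
    patients.  Raises on an empty evaluation population.
    """
    out = _eligible(outcomes, config.tau)
    if len(out) == 0:
        raise XenoeqError("empty evaluation population after censor policy")
    le = predicted_le.reindex(out["patient_id"])
    if le.isna().any():
        raise XenoeqError("predictions and outcomes are keyed differently")
    identified = (le.to_numpy(float) <= config.tau)
    died = ((out["outcome_type"] == "death_or_delisting")
            & (out["outcome_time"] <= config.tau)).to_numpy()
    n_id = int(identified.sum())
    n_died = int(died.sum())
    n_correct = int((identified & died).sum())
    return MetricsReport(
        n_identified=n_id, n_died_within_tau=n_died, n_correct=n_correct,
        hit_rate=(n_correct / n_id) if n_id else None,
        capture_rate=(n_correct / n_died) if n_died else None,
        suppressed=n_correct < config.min_correct,
        tau=config.tau, n_evaluated=int(len(out)),
        censor_policy=config.censor_policy)


def oracle_confusion(predicted_le: pd.Series, outcomes: pd.DataFrame,
                     tau: float) -> tuple[int, int, int]:
    """Brute-force per-patient recount of (identified, died, correct).

    Deliberately written as an explicit loop, independent of
    :func:`evaluate`'s vectorized path, for use as a testing oracle.
    """
    n_id = n_died = n_correct = 0
    for row in _eligible(outcomes, tau).itertuples():
        ident = predicted_le.loc[row.patient_id] <= tau
        dead = (row.outcome_type == "death_or_delisting"
                and row.outcome_time <= tau)
        n_id += bool(ident)
        n_died += bool(dead)
        n_correct += bool(ident and dead)
    return n_id, n_died, n_correct
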