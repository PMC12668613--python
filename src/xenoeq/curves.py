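"""Survival and cumulative-incidence curves on a common time grid.

All curves in this package live on a regular grid of times in decimal years
starting at 0 (monthly by default, i.e. a step of 1/12 year).  Life
expectancy is the restricted mean survival time: the trapezoidal integral of
the survival curve over its grid.  Beyond the last estimated point, curves
are carried forward at their last value (no tail extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConditioningError, XenoeqError

MONTH = 1.0 / 12.0


def time_grid(horizon: float, step: float = MONTH) -> np.ndarray:
    """Regular grid [0, step, 2*step, ..., horizon]."""
    n = int(round(horizon / step))
    if n <= 0 or abs(n * step - horizon) > 1e-9:
        raise XenoeqError(
            f"time step {step} does not evenly divide horizon {horizon}"
        )
    return np.linspace(0.0, horizon, n + 1)


def _check_grid(times: np.ndarray) -> None:
    if times.ndim != 1 or times.size < 2:
        raise XenoeqError("curve needs at least two time points")
    if times[0] != 0.0:
        raise XenoeqError("curve time grid must start at 0")
    if np.any(np.diff(times) <= 0):
        raise XenoeqError("curve times must be strictly increasing")


@dataclass(frozen=True)
class SurvivalCurve:
    """P(T > t) on a grid starting at 0; S(0)=1, non-increasing, in [0,1]."""

    times: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        _check_grid(t)
        if p.shape != t.shape:
            raise XenoeqError("times and probabilities must have equal length")
        if abs(p[0] - 1.0) > 1e-9:
            raise XenoeqError("survival curve must start at 1")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise XenoeqError("survival probabilities must lie in [0,1]")
        if np.any(np.diff(p) > 1e-9):
            raise XenoeqError("survival curve must be non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, 1.0))

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def at(self, t) -> np.ndarray:
        """Linear interpolation within the grid; carried forward beyond it."""
        return np.interp(t, self.times, self.probabilities)


@dataclass(frozen=True)
class IncidenceCurve:
    """Cumulative probability of an event (e.g. transplant) by time t."""

    times: np.ndarray
    cumulative_probability: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cumulative_probability, dtype=float)
        _check_grid(t)
        if c.shape != t.shape:
            raise XenoeqError("times and probabilities must have equal length")
        if abs(c[0]) > 1e-9:
            raise XenoeqError("incidence curve must start at 0")
        if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
            raise XenoeqError("cumulative probabilities must lie in [0,1]")
        if np.any(np.diff(c) < -1e-9):
            raise XenoeqError("incidence curve must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_probability", np.clip(c, 0.0, 1.0))

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.cumulative_probability)


@dataclass(frozen=True)
class CurveWithBand:
    """A curve with pointwise 95% confidence bounds, or a suppressed slot.

    ``suppressed`` is set instead of a curve when the underlying stratum has
    fewer events than the reporting threshold (15 by default), mirroring the
    small-cell suppression rule used when publishing registry analyses.
    """

    curve: SurvivalCurve | IncidenceCurve | None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    suppressed: bool = False
    n_events: int = 0

    def __post_init__(self):
        if self.suppressed:
            return
        if self.curve is None:
            raise XenoeqError("non-suppressed band requires a curve")
        y = (
            self.curve.probabilities
            if isinstance(self.curve, SurvivalCurve)
            else self.curve.cumulative_probability
        )
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != y.shape or hi.shape != y.shape:
            raise XenoeqError("band bounds must match the curve grid")
        if np.any(lo > y + 1e-9) or np.any(hi < y - 1e-9):
            raise XenoeqError("band must bracket the curve pointwise")


def life_expectancy(curve: SurvivalCurve) -> float:
    """Restricted mean survival time: trapezoidal area under the curve.

    Units are years; the value lies in [0, horizon].
    """
    return float(np.trapezoid(curve.probabilities, curve.times))


def conditional_curve(curve: SurvivalCurve, elapsed: float) -> SurvivalCurve:
    """Survival conditional on being alive at ``elapsed``: S(e+t)/S(e).

    The result is re-gridded from 0 with horizon ``curve.horizon - elapsed``.
    """
    if elapsed < 0:
        raise XenoeqError("elapsed time must be non-negative")
    if elapsed == 0:
        return curve
    if elapsed >= curve.horizon:
        raise DegenerateConditioningError(
            f"elapsed {elapsed} is at or beyond the curve horizon {curve.horizon}"
        )
    s_e = curve.at(elapsed)
    if s_e <= 0:
        raise DegenerateConditioningError(
            f"survival is zero at elapsed time {elapsed}"
        )
    step = float(curve.times[1] - curve.times[0])
    n = int(np.floor((curve.horizon - elapsed) / step + 1e-9))
    if n < 1:
        raise DegenerateConditioningError("no grid remains after conditioning")
    new_times = np.arange(n + 1) * step
    probs = curve.at(elapsed + new_times) / s_e
    probs = np.minimum.accumulate(np.clip(probs, 0.0, 1.0))
    probs[0] = 1.0
    return SurvivalCurve(new_times, probs)


def incidence_from_survival(curve: SurvivalCurve) -> IncidenceCurve:
    """1 - S(t) as a cumulative incidence curve."""
    return IncidenceCurve(curve.times, 1.0 - curve.probabilities)


def condition_matrix(M: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Row-wise conditional survival with per-row grid offsets.

    ``M`` holds survival-type values (n_rows, n_times) on a regular grid;
    row i is replaced by M[i, k_i + j] / M[i, k_i] with the tail carried
    forward at the last grid value (zero hazard beyond the horizon).  Rows
    whose survival is already zero at the offset collapse to zero.
    """
    M = np.asarray(M, dtype=float)
    n, t = M.shape
    k = np.asarray(offsets, dtype=int)
    j = np.minimum(np.arange(t)[None, :] + k[:, None], t - 1)
    shifted = M[np.arange(n)[:, None], j]
    denom = M[np.arange(n), k][:, None]
    out = np.where(denom > 0, shifted / np.maximum(denom, 1e-300), 0.0)
    return np.minimum.accumulate(np.clip(out, 0.0, 1.0), axis=1)
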