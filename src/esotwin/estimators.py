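"""Classical survival estimators: Kaplan-Meier, Nelson-Aalen, reverse-KM.

These are implemented directly on risk-set tabulations (deaths precede
censorings at tied times, i.e. everyone with time >= t is at risk at t) so
that the degenerate single-node survival tree can be checked against them
bit for bit; lifelines provides an independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step function S(t) on an increasing grid of months.

    S(0) = 1 implicitly before the first grid point; ``survival[k]`` is the
    value on [times[k], times[k+1]).
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("times and survival must be matching 1-d arrays")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if t.size and ((s < -1e-12).any() or (s > 1 + 1e-12).any()):
            raise ValueError("survival values must lie in [0, 1]")
        if t.size and (np.diff(s) > 1e-12).any():
            raise ValueError("survival must be non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)

    def __call__(self, t: float) -> float:
        """Step evaluation, right-continuous: S(t) for scalar t >= 0."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _risk_table(times: np.ndarray, events: np.ndarray):
    """Distinct event times with death counts d and risk-set sizes Y."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    uniq, starts = np.unique(t_s, return_index=True)
    d = np.add.reduceat(e_s, starts)
    y = len(t_s) - starts
    keep = d > 0
    return uniq[keep], d[keep].astype(float), y[keep].astype(float)


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator over the distinct event times."""
    te, d, y = _risk_table(times, events)
    return SurvivalCurve(te, np.cumprod(1.0 - d / y))


def na_estimate(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Nelson-Aalen cumulative hazard H(t) = sum_{event times <= t} d/Y."""
    te, d, y = _risk_table(times, events)
    return te, np.cumsum(d / y)


def eval_cumhaz(event_times: np.ndarray, cumhaz: np.ndarray,
                grid: np.ndarray) -> np.ndarray:
    """Step-interpolate a cumulative hazard onto ``grid`` (H=0 before the
    first event time)."""
    idx = np.searchsorted(event_times, grid, side="right")
    return np.concatenate(([0.0], cumhaz))[idx]


def followup_summary(times, events) -> dict:
    """Observed and potential follow-up for a cohort.

    Observed follow-up is summarized over the censored patients (median plus
    the times beyond which 50/25/10% of them were still being followed);
    potential follow-up — the median follow-up had there been no deaths — is
    the median of the reverse Kaplan-Meier estimate, in which censoring is
    the event and deaths censor.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty sample")
    censored = times[events == 0]
    def _q(q: float) -> float:
        return float(np.quantile(censored, q)) if censored.size else float("nan")

    # "50% were followed > t" style quantiles of the censored times
    obs = {
        "median_observed": _q(0.50),
        "time_exceeded_by_50pct": _q(0.50),
        "time_exceeded_by_25pct": _q(0.75),
        "time_exceeded_by_10pct": _q(0.90),
    }
    rkm = km_estimate(times, 1 - events)
    below = np.flatnonzero(rkm.survival <= 0.5)
    potential = float(rkm.times[below[0]]) if below.size else float("inf")
    return {**obs, "median_potential": potential}
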