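"""Core containers shared across the pipeline.

Time is measured in years everywhere inside the package; inputs denominated
in months are converted on load (months / 12). Money is GBP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MONTHS_PER_YEAR = 12.0
WEEKS_PER_YEAR = 365.25 / 7.0


class DataError(ValueError):
    """Invalid survival data or curve inputs."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored time-to-event records for one arm and one endpoint.

    Parameters
    ----------
    times : array of positive floats (years)
    events : array of 0/1 flags (1 = event observed, 0 = censored)
    arm : arm label, e.g. ``"intervention"``
    endpoint : one of ``"OS"``, ``"PFS"``, ``"TTD"``
    """

    times: np.ndarray
    events: np.ndarray
    arm: str = "arm"
    endpoint: str = "OS"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.ndim != 1 or t.size == 0:
            raise DataError("times must be a non-empty 1-d array")
        if t.shape != e.shape:
            raise DataError("times and events must have the same length")
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise DataError("all times must be positive and finite")
        if not np.isin(e, (0, 1)).all():
            raise DataError("event flags must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def person_time(self) -> float:
        return float(self.times.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "time": self.times,
                "event": self.events,
                "arm": self.arm,
                "endpoint": self.endpoint,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arm: Optional[str] = None,
                   endpoint: Optional[str] = None) -> "SurvivalDataset":
        sub = df
        if arm is not None:
            sub = sub[sub["arm"] == arm]
        if endpoint is not None:
            sub = sub[sub["endpoint"] == endpoint]
        if sub.empty:
            raise DataError(f"no records for arm={arm!r}, endpoint={endpoint!r}")
        a = arm if arm is not None else str(sub["arm"].iloc[0])
        ep = endpoint if endpoint is not None else str(sub["endpoint"].iloc[0])
        return cls(sub["time"].to_numpy(float), sub["event"].to_numpy(int), a, ep)


@dataclass(frozen=True)
class DigitizedCurve:
    """Step coordinates and numbers-at-risk as read off a published KM figure.

    ``n_at_risk`` at a reported time t counts subjects whose observed time is
    strictly greater than t (the post-event count at t); digitization and
    reconstruction share this convention.
    """

    times: np.ndarray          # coordinate times, starting at 0
    survival: np.ndarray       # KM survival at each coordinate, starting at 1
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    total_events: Optional[int] = None
    arm: str = "arm"
    endpoint: str = "OS"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        rt = np.asarray(self.risk_times, dtype=float)
        nr = np.asarray(self.n_at_risk, dtype=int)
        if t.size < 1 or t[0] != 0.0 or abs(s[0] - 1.0) > 1e-12:
            raise DataError("coordinates must start at (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise DataError("coordinate times must be strictly increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise DataError("survival coordinates must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise DataError("survival coordinates must be non-increasing")
        if rt.size < 1 or rt[0] != 0.0 or nr[0] <= 0:
            raise DataError("risk table must start at t=0 with n > 0")
        if np.any(np.diff(rt) <= 0) or np.any(np.diff(nr) > 0) or np.any(nr < 0):
            raise DataError("risk table must be non-increasing over increasing times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", np.clip(s, 0.0, 1.0))
        object.__setattr__(self, "risk_times", rt)
        object.__setattr__(self, "n_at_risk", nr)

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})

    def risk_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk})


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous non-increasing step function with value 1 before the
    first knot (the Kaplan-Meier output representation)."""

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if k.shape != v.shape or k.ndim != 1:
            raise DataError("knots and values must be matching 1-d arrays")
        if k.size and np.any(np.diff(k) <= 0):
            raise DataError("knots must be strictly increasing")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12) or np.any(np.diff(v) > 1e-12):
            raise DataError("values must be non-increasing within [0, 1]")
        object.__setattr__(self, "knots", k)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return out if out.shape else float(out)

    def sf(self, t) -> np.ndarray:
        """Survival-function alias so a StepFunction can stand in wherever a
        parametric survival object is accepted (e.g. a KM-based TTD curve)."""
        return self.__call__(t)


@dataclass(frozen=True)
class HazardCurve:
    """Empirical hazard on a time grid (per year)."""

    times: np.ndarray
    hazard: np.ndarray
    method: str  # "piecewise_exponential" | "bspline_smoothed"
    bin_edges: Optional[np.ndarray] = None
    person_time: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.hazard, dtype=float)
        if t.shape != h.shape:
            raise DataError("times and hazard must have the same shape")
        if t.size and np.any(np.diff(t) <= 0):
            raise DataError("hazard times must be strictly increasing")
        if np.any(h < 0):
            raise DataError("hazard must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "hazard", h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "hazard": self.hazard})
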