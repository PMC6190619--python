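"""Trial time-to-event containers, the censored-data likelihood, and life-table expansion.

The canonical internal time unit is years. Follow-up times must be strictly
positive because every survival model in this package works on the log-time
scale; zero times are rejected at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ARM_CONTROL = 0
ARM_TREATMENT = 1


class DataValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: follow-up time (years), event flag (1=death, 0=censored), arm (0/1)."""

    time: float
    event: int
    arm: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise DataValidationError(f"follow-up time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise DataValidationError(f"event must be 0 or 1, got {self.event}")
        if self.arm not in (ARM_CONTROL, ARM_TREATMENT):
            raise DataValidationError(f"arm must be 0 or 1, got {self.arm}")


class TrialData:
    """Two-arm (or one-arm) individual-patient time-to-event data.

    Stored internally as aligned numpy arrays ``time`` (float, years),
    ``event`` (0/1) and ``arm`` (0=control, 1=treatment).
    """

    def __init__(
        self,
        time: Sequence[float],
        event: Sequence[int],
        arm: Sequence[int],
        max_follow_up: float | None = None,
    ) -> None:
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.arm = np.asarray(arm, dtype=int)
        if not (self.time.shape == self.event.shape == self.arm.shape):
            raise DataValidationError("time, event, arm must have equal length")
        if self.time.size and (not np.all(np.isfinite(self.time)) or np.any(self.time <= 0)):
            raise DataValidationError("all follow-up times must be finite and > 0")
        if not np.all(np.isin(self.event, (0, 1))):
            raise DataValidationError("event indicators must be 0 or 1")
        if not np.all(np.isin(self.arm, (ARM_CONTROL, ARM_TREATMENT))):
            raise DataValidationError("arm codes must be 0 (control) or 1 (treatment)")
        observed_max = float(self.time.max()) if self.time.size else 0.0
        self.max_follow_up = observed_max if max_follow_up is None else float(max_follow_up)
        if self.max_follow_up < observed_max:
            raise DataValidationError("max_follow_up must be >= max observed time")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord], max_follow_up: float | None = None) -> "TrialData":
        recs = list(records)
        return cls(
            [r.time for r in recs], [r.event for r in recs], [r.arm for r in recs], max_follow_up
        )

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        """Read IPD from CSV with required header ``time,event,arm``."""
        df = pd.read_csv(path)
        missing = {"time", "event", "arm"} - set(df.columns)
        if missing:
            raise DataValidationError(f"IPD CSV missing columns: {sorted(missing)}")
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), df["arm"].to_numpy())

    @classmethod
    def concat(cls, parts: Sequence["TrialData"]) -> "TrialData":
        if not parts:
            return cls([], [], [])
        return cls(
            np.concatenate([p.time for p in parts]),
            np.concatenate([p.event for p in parts]),
            np.concatenate([p.arm for p in parts]),
            max(p.max_follow_up for p in parts),
        )

    # -- views -------------------------------------------------------------
    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def arm_mask(self, arm: int) -> np.ndarray:
        return self.arm == arm

    def subset(self, arm: int) -> "TrialData":
        m = self.arm_mask(arm)
        return TrialData(self.time[m], self.event[m], self.arm[m], self.max_follow_up)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def require_two_arms(self) -> None:
        if not (np.any(self.arm == ARM_CONTROL) and np.any(self.arm == ARM_TREATMENT)):
            raise DataValidationError("two-arm fit requires records in both arms")


@dataclass(frozen=True)
class LifeTableRow:
    """One life-table interval: [t_start, t_end), counts at risk / events / censored."""

    t_start: float
    t_end: float
    n_risk: int
    n_event: int
    n_censor: int

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise DataValidationError(f"interval bounds must satisfy t_start < t_end ({self})")
        if self.n_event < 0 or self.n_censor < 0 or self.n_event + self.n_censor > self.n_risk:
            raise DataValidationError(f"counts must satisfy 0 <= n_event + n_censor <= n_risk ({self})")


def read_life_table_csv(path) -> list[LifeTableRow]:
    """Read a life table CSV with columns t_start,t_end,n_risk,n_event,n_censor."""
    df = pd.read_csv(path)
    cols = ["t_start", "t_end", "n_risk", "n_event", "n_censor"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataValidationError(f"life-table CSV missing columns: {sorted(missing)}")
    return [
        LifeTableRow(r.t_start, r.t_end, int(r.n_risk), int(r.n_event), int(r.n_censor))
        for r in df[cols].itertuples(index=False)
    ]


def expand_life_table(
    rows: Sequence[LifeTableRow],
    arm: int = ARM_CONTROL,
    event_placement: str = "midpoint",
) -> TrialData:
    """Expand an interval life table into pseudo individual-patient data.

    Events are placed at the interval midpoint by default (``event_placement``
    may be ``"midpoint"`` or ``"end"``); within-interval censorings at the
    interval end. Survivors of the final interval are censored at its end, so
    the expanded dataset always contains exactly the initial number at risk.
    """
    if event_placement not in ("midpoint", "end"):
        raise DataValidationError(f"unknown event_placement {event_placement!r}")
    if not rows:
        return TrialData([], [], [])
    times: list[float] = []
    events: list[int] = []
    for i, row in enumerate(rows):
        if i > 0:
            prev = rows[i - 1]
            expected = prev.n_risk - prev.n_event - prev.n_censor
            if row.n_risk != expected:
                raise DataValidationError(
                    f"life-table row {i} chains inconsistently: n_risk={row.n_risk}, "
                    f"expected {expected} from row {i - 1}"
                )
            if row.t_start != prev.t_end:
                raise DataValidationError(
                    f"life-table row {i} interval start {row.t_start} != previous end {prev.t_end}"
                )
        t_event = 0.5 * (row.t_start + row.t_end) if event_placement == "midpoint" else row.t_end
        times.extend([t_event] * row.n_event)
        events.extend([1] * row.n_event)
        times.extend([row.t_end] * row.n_censor)
        events.extend([0] * row.n_censor)
    last = rows[-1]
    survivors = last.n_risk - last.n_event - last.n_censor
    times.extend([last.t_end] * survivors)
    events.extend([0] * survivors)
    return TrialData(times, events, [arm] * len(times), max_follow_up=last.t_end)


def trial_log_likelihood(data: TrialData, model, params: np.ndarray) -> float:
    """Censored-data log likelihood: sum of log h(t) - H(t) for events, -H(t) for censorings.

    Returns ``-inf`` (an invalid-parameter flag, not an exception) when the
    model produces a non-finite hazard or cumulative hazard at any observed
    time, so samplers can simply reject the draw.
    """
    if len(data) == 0:
        return 0.0
    total = 0.0
    with np.errstate(all="ignore"):
        for arm in (ARM_CONTROL, ARM_TREATMENT):
            m = data.arm_mask(arm)
            if not m.any():
                continue
            t = data.time[m]
            ev = data.event[m] == 1
            H = model.cum_hazard(params, t, arm)
            contrib = -np.sum(H)
            if ev.any():
                logh = model.log_hazard(params, t[ev], arm)
                contrib += np.sum(logh)
            if not np.isfinite(contrib):
                return -np.inf
            total += contrib
    return float(total)
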