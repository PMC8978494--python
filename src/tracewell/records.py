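"""Core record types shared by the generators and the feature builders.

Timestamps are timezone-naive :class:`pandas.Timestamp` values interpreted
in a single configured clock (the synthetic generator carries no zones;
adapters for real exports must localize before featurization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["UserRecord", "MessageEvent", "AppUsageEvent", "Cohort"]


@dataclass
class UserRecord:
    """One participant: demographics, scale totals and screening scores.

    ``phq``/``gad``/``pss`` are ``None`` when the user did not complete the
    corresponding questionnaire.  ``reference_time`` anchors all trace
    windows (it stands in for the assessment-app install time).
    """

    user_id: str
    age: int | None
    gender: str | None  # "male" | "female"
    n_vk_friends: int
    n_subscriptions: int
    swls_raw: int
    who5_raw: int
    phq: int | None
    gad: int | None
    pss: int | None
    reference_time: pd.Timestamp

    def __post_init__(self) -> None:
        if self.reference_time is None:
            raise ValueError("reference_time is required")
        if not 5 <= self.swls_raw <= 35:
            raise ValueError("swls_raw outside [5, 35]")
        if not 5 <= self.who5_raw <= 30:
            raise ValueError("who5_raw outside [5, 30]")
        for name, val, hi in (("phq", self.phq, 27), ("gad", self.gad, 21),
                              ("pss", self.pss, 40)):
            if val is not None and not 0 <= val <= hi:
                raise ValueError(f"{name} outside [0, {hi}]")


@dataclass
class MessageEvent:
    """A private message: sender, correspondent (alter), time and lemmas."""

    user_id: str
    alter_id: str
    timestamp: pd.Timestamp
    tokens: list[str]


@dataclass
class AppUsageEvent:
    """A foreground app session; duration in integer milliseconds."""

    user_id: str
    package: str
    start: pd.Timestamp
    duration_ms: int

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


@dataclass
class Cohort:
    """Users plus their message and app-usage streams.

    ``swls_items`` / ``who5_items`` are per-user item-level scores (five
    columns each) whose rows sum to the raw totals; they exist so that
    internal-consistency statistics are computable.
    """

    users: list[UserRecord] = field(default_factory=list)
    messages: list[MessageEvent] = field(default_factory=list)
    usage: list[AppUsageEvent] = field(default_factory=list)
    swls_items: np.ndarray | None = None
    who5_items: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.users)

    def users_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.users:
            rows.append({
                "user_id": u.user_id, "age": u.age, "gender": u.gender,
                "n_vk_friends": u.n_vk_friends,
                "n_subscriptions": u.n_subscriptions,
                "swls_raw": u.swls_raw, "who5_raw": u.who5_raw,
                "phq": u.phq, "gad": u.gad, "pss": u.pss,
                "reference_time": u.reference_time,
            })
        cols = ["user_id", "age", "gender", "n_vk_friends", "n_subscriptions",
                "swls_raw", "who5_raw", "phq", "gad", "pss", "reference_time"]
        return pd.DataFrame(rows, columns=cols)

    def messages_by_user(self) -> dict[str, list[MessageEvent]]:
        out: dict[str, list[MessageEvent]] = {u.user_id: [] for u in self.users}
        for m in self.messages:
            out.setdefault(m.user_id, []).append(m)
        return out

    def usage_by_user(self) -> dict[str, list[AppUsageEvent]]:
        out: dict[str, list[AppUsageEvent]] = {u.user_id: [] for u in self.users}
        for e in self.usage:
            out.setdefault(e.user_id, []).append(e)
        return out
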