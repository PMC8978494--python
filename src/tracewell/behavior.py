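"""The 40 user-metadata and overall-activity features.

Covers demographics and profile counts, trailing-30-day message volume,
weighted month-over-month growth, one week of overall app usage broken
into eight 3-hour slots of the day (totals and ratios), and distinct
correspondent (alter) counts for each of the 12 thirty-day months before
the reference time.

Sessions crossing a slot (or midnight) boundary are split proportionally,
so slot totals conserve overall usage time exactly.  Months are 30-day
windows counted backward from each user's reference time, not calendar
months.  All timestamps are interpreted in one configured clock.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .records import AppUsageEvent, MessageEvent, UserRecord

__all__ = [
    "SLOT_LABELS",
    "BEHAVIOR_FEATURES",
    "GENDER_CODES",
    "monthly_alters",
    "weighted_growth",
    "split_session_into_slots",
    "slot_usage_features",
    "activity_features",
    "behavior_feature_frame",
]

SECONDS_PER_SLOT = 3 * 3600
SLOT_LABELS = tuple(f"{3 * i}-{3 * (i + 1)}" for i in range(8))

#: gender encoding used in the feature matrix (documented, swappable)
GENDER_CODES = {"male": 0.0, "female": 1.0}

BEHAVIOR_FEATURES = (
    "Age", "Gender", "NVkFriends", "AllAlters", "Subscriptions",
    "Mess_1", "MessChars_1", "growth-2to-1weighted", "altersdiff",
    "AppUsage1Week", "AllAppTime1Week", "RatioAppTime1Week",
    *(f"AppUsage{s}" for s in SLOT_LABELS),
    *(f"AppUsage{s}Ratio" for s in SLOT_LABELS),
    *(f"Alters-{m}" for m in range(1, 13)),
)
assert len(BEHAVIOR_FEATURES) == 40


def _month_window(reference_time: pd.Timestamp, month: int):
    """Half-open window of 30-day month ``-month``: (ref - m*30d, ref - (m-1)*30d]."""
    end = reference_time - pd.Timedelta(days=30 * (month - 1))
    start = reference_time - pd.Timedelta(days=30 * month)
    return start, end


def monthly_alters(messages: Sequence[MessageEvent],
                   reference_time: pd.Timestamp,
                   n_months: int = 12) -> np.ndarray:
    """Distinct alters with >= 1 message in each trailing 30-day month."""
    sets: list[set] = [set() for _ in range(n_months)]
    for msg in messages:
        delta = (reference_time - msg.timestamp).total_seconds()
        if delta < 0:
            continue
        month = int(delta // (30 * 86400))  # 0-based: month -1 is index 0
        if month < n_months:
            sets[month].add(msg.alter_id)
    return np.array([len(s) for s in sets])


def weighted_growth(value_m1: float, value_m2: float) -> float:
    """Symmetric relative difference ``(v1 - v2) / (v1 + v2)`` in [-1, 1];
    0 when both values are 0."""
    if value_m1 < 0 or value_m2 < 0:
        raise ValueError("growth inputs must be non-negative")
    total = value_m1 + value_m2
    return 0.0 if total == 0 else (value_m1 - value_m2) / total


def split_session_into_slots(start: pd.Timestamp,
                             duration_s: float) -> list[tuple[int, float]]:
    """Distribute a session's seconds over the 8 daily 3-hour slots.

    Sessions crossing slot or midnight boundaries are split proportionally;
    the returned (slot index, seconds) pairs sum exactly to ``duration_s``.
    """
    out: list[tuple[int, float]] = []
    sod = (start - start.normalize()).total_seconds()
    remaining = float(duration_s)
    while remaining > 0:
        slot = int(sod // SECONDS_PER_SLOT) % 8
        to_boundary = (slot + 1) * SECONDS_PER_SLOT - sod
        take = min(remaining, to_boundary)
        out.append((slot, take))
        remaining -= take
        sod = (sod + take) % 86400
    return out


def slot_usage_features(events: Sequence[AppUsageEvent]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-slot usage seconds and their ratios to total usage (0/0 -> 0)."""
    totals = np.zeros(8)
    for ev in events:
        for slot, sec in split_session_into_slots(ev.start,
                                                  ev.duration_ms / 1000.0):
            totals[slot] += sec
    grand = totals.sum()
    ratios = totals / grand if grand > 0 else np.zeros(8)
    return totals, ratios


def _message_chars(msg: MessageEvent) -> int:
    # lemma streams carry no raw text; characters = total lemma length
    return sum(len(t) for t in msg.tokens)


def activity_features(user: UserRecord,
                      messages: Sequence[MessageEvent],
                      usage: Sequence[AppUsageEvent],
                      observation_days: int = 7) -> pd.Series:
    """The full 40-feature row for one user.

    Missing demographics become NaN (imputation is the modeling stage's
    job); empty streams yield zero counts and zero ratios.
    """
    ref = user.reference_time
    feats: dict[str, float] = {}
    feats["Age"] = float(user.age) if user.age is not None else np.nan
    feats["Gender"] = (GENDER_CODES[user.gender]
                       if user.gender in GENDER_CODES else np.nan)
    feats["NVkFriends"] = float(user.n_vk_friends)
    feats["Subscriptions"] = float(user.n_subscriptions)

    alters_by_month = monthly_alters(messages, ref)
    year_start = ref - pd.Timedelta(days=360)  # 12 x 30-day months
    all_alters = {m.alter_id for m in messages
                  if year_start < m.timestamp <= ref}
    feats["AllAlters"] = float(len(all_alters))

    m1_start, _ = _month_window(ref, 1)
    m2_start, m2_end = _month_window(ref, 2)
    mess_1 = [m for m in messages if m1_start < m.timestamp <= ref]
    mess_2 = [m for m in messages if m2_start < m.timestamp <= m2_end]
    feats["Mess_1"] = float(len(mess_1))
    chars_1 = float(sum(_message_chars(m) for m in mess_1))
    chars_2 = float(sum(_message_chars(m) for m in mess_2))
    feats["MessChars_1"] = chars_1
    feats["growth-2to-1weighted"] = weighted_growth(chars_1, chars_2)
    feats["altersdiff"] = weighted_growth(float(alters_by_month[0]),
                                          float(alters_by_month[1]))

    feats["AppUsage1Week"] = float(len(usage))
    slot_totals, slot_ratios = slot_usage_features(usage)
    total_time = float(slot_totals.sum())
    feats["AllAppTime1Week"] = total_time
    feats["RatioAppTime1Week"] = (total_time / (observation_days * 86400.0)
                                  if observation_days > 0 else 0.0)
    for s, label in enumerate(SLOT_LABELS):
        feats[f"AppUsage{label}"] = float(slot_totals[s])
    for s, label in enumerate(SLOT_LABELS):
        feats[f"AppUsage{label}Ratio"] = float(slot_ratios[s])
    for m in range(1, 13):
        feats[f"Alters-{m}"] = float(alters_by_month[m - 1])

    return pd.Series(feats, index=list(BEHAVIOR_FEATURES))


def behavior_feature_frame(users: Sequence[UserRecord],
                           messages_by_user: dict,
                           usage_by_user: dict,
                           observation_days: int = 7) -> pd.DataFrame:
    rows = {u.user_id: activity_features(
        u, messages_by_user.get(u.user_id, []),
        usage_by_user.get(u.user_id, []), observation_days)
        for u in users}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(BEHAVIOR_FEATURES))
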