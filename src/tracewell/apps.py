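"""App categorization and the 225 category x time-slot usage features.

Every package maps to one of nine app categories (unmapped packages fall
back to Other).  From one observation week of foreground sessions the
feature row contains:

* 9 raw per-category totals (seconds over the whole window),
* 72 category x slot values, averaged per day of the window,
* 72 of those normalized by the category's total,
* 72 normalized by the slot's total across categories,

for 9 + 72*3 = 225 features.  The per-day averaging denominator is the
full window length in days (default 7), not the number of active days;
0/0 ratios are 0.  Session seconds are split across slot boundaries
proportionally, exactly as in :mod:`tracewell.behavior`, so category
totals conserve overall usage time.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import SLOT_LABELS, split_session_into_slots
from .records import AppUsageEvent

__all__ = [
    "CATEGORIES",
    "AppCategoryMap",
    "categorize_app",
    "app_feature_names",
    "category_slot_features",
    "app_feature_frame",
]

CATEGORIES = (
    "Game", "Education+Productivity", "Tools", "Entertainment",
    "Personalization", "Health+Medical", "Social+Communication+Dating",
    "Photography", "Other",
)
_CAT_LABELS = tuple(c.upper() for c in CATEGORIES)
FALLBACK = "Other"


@dataclass
class AppCategoryMap:
    """Package -> category mapping; editable TSV on disk."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories in map: {sorted(bad)}")

    def categorize(self, package: str) -> str:
        return self.mapping.get(package, FALLBACK)

    @classmethod
    def from_tsv(cls, path) -> "AppCategoryMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["package", "category"], dtype=str,
                         comment="#")
        return cls(dict(zip(df["package"], df["category"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"package": list(self.mapping),
                      "category": list(self.mapping.values())}
                     ).to_csv(path, sep="\t", header=False, index=False)


def categorize_app(package: str, cat_map: AppCategoryMap) -> str:
    return cat_map.categorize(package)


def app_feature_names() -> list[str]:
    """The 225 canonical feature names: CATEGORY, CATEGORY_slot,
    CATEGORY_slot/CATEGORY and CATEGORY_slot/slot."""
    names = list(_CAT_LABELS)
    names += [f"{c}_{s}" for c in _CAT_LABELS for s in SLOT_LABELS]
    names += [f"{c}_{s}/{c}" for c in _CAT_LABELS for s in SLOT_LABELS]
    names += [f"{c}_{s}/{s}" for c in _CAT_LABELS for s in SLOT_LABELS]
    return names


def category_slot_features(events: Sequence[AppUsageEvent],
                           cat_map: AppCategoryMap,
                           window_days: int = 7) -> pd.Series:
    """The 225-value app-category feature row for one user."""
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    seconds = np.zeros((len(CATEGORIES), 8))
    for ev in events:
        ci = cat_index[cat_map.categorize(ev.package)]
        for slot, sec in split_session_into_slots(ev.start,
                                                  ev.duration_ms / 1000.0):
            seconds[ci, slot] += sec

    cat_totals = seconds.sum(axis=1)  # raw seconds over the whole window
    per_day = seconds / window_days
    cat_per_day = cat_totals / window_days
    slot_per_day = per_day.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        by_cat = np.where(cat_per_day[:, None] > 0,
                          per_day / cat_per_day[:, None], 0.0)
        by_slot = np.where(slot_per_day[None, :] > 0,
                           per_day / slot_per_day[None, :], 0.0)

    values = np.concatenate([cat_totals, per_day.ravel(),
                             by_cat.ravel(), by_slot.ravel()])
    return pd.Series(values, index=app_feature_names())


def app_feature_frame(users, usage_by_user: dict, cat_map: AppCategoryMap,
                      window_days: int = 7) -> pd.DataFrame:
    rows = {u.user_id: category_slot_features(
        usage_by_user.get(u.user_id, []), cat_map, window_days)
        for u in users}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=app_feature_names())
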