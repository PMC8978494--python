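"""Feature-family accounting and provenance.

The fixed families contribute 40 (behavior) + 225 (app categories) +
6 (sentiment) + 8 (closed-vocabulary categories) features; the word and
cluster families are sized by the heldout selection, so the grand totals
depend on the target scale (660 for SWLS and 651 for WHO-5 at the
reference selection sizes of 353 words and 28 / 19 clusters).
"""

from __future__ import annotations

import re

from .apps import app_feature_names
from .behavior import BEHAVIOR_FEATURES
from .text import SENTIMENT_FEATURES

__all__ = ["FIXED_FAMILY_SIZES", "feature_totals", "family_of"]

FIXED_FAMILY_SIZES = {
    "behavior": len(BEHAVIOR_FEATURES),   # 40
    "appcats": len(app_feature_names()),  # 225
    "sentiment": len(SENTIMENT_FEATURES),  # 6
    "ruliwc": 8,
}

_APP_NAMES = frozenset(app_feature_names())
_BEHAVIOR_NAMES = frozenset(BEHAVIOR_FEATURES)
_SENTIMENT_NAMES = frozenset(SENTIMENT_FEATURES)
_CLUSTER_RE = re.compile(r"^cluster_\d+$")


def feature_totals(n_words: int, n_clusters: int) -> dict[str, int]:
    """Per-family sizes and the grand total for one target scale."""
    sizes = dict(FIXED_FAMILY_SIZES)
    sizes["words"] = int(n_words)
    sizes["clusters"] = int(n_clusters)
    sizes["total"] = sum(sizes.values())
    return sizes


def family_of(feature_name: str) -> str:
    """Map a feature name to its family by the canonical naming grammar."""
    if feature_name in _BEHAVIOR_NAMES:
        return "behavior"
    if feature_name in _APP_NAMES:
        return "appcats"
    if feature_name in _SENTIMENT_NAMES:
        return "sentiment"
    if feature_name.endswith("_RuLIWC"):
        return "ruliwc"
    if _CLUSTER_RE.match(feature_name):
        return "clusters"
    return "words"
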