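"""End-to-end featurization glue: cohort -> per-user feature matrix.

Combines the fixed feature families (behavior, app categories, sentiment,
closed-vocabulary categories); the heldout-dependent families (words,
clusters) are attached separately because they require a disjoint cohort
for selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .apps import AppCategoryMap, app_feature_frame
from .behavior import behavior_feature_frame
from .records import Cohort
from .scales import SWLS, WHO5, normalize_score
from .text import (Lexicon, TfidfModel, build_documents,
                   lexicon_category_features, sentiment_proportions)

__all__ = ["normalized_targets", "featurize_cohort"]


def normalized_targets(cohort: Cohort) -> pd.DataFrame:
    """Normalized SWLS and WHO-5 per user, indexed by user id."""
    df = cohort.users_frame().set_index("user_id")
    return pd.DataFrame({
        "swls": normalize_score(SWLS, df["swls_raw"].to_numpy()),
        "who5": normalize_score(WHO5, df["who5_raw"].to_numpy()),
    }, index=df.index)


def featurize_cohort(cohort: Cohort,
                     sentiment_lexicon: Lexicon,
                     category_lexicon: Lexicon,
                     cat_map: AppCategoryMap,
                     observation_days: int = 7) -> pd.DataFrame:
    """Fixed-family feature matrix: 40 + 225 + 6 + 8 columns per user."""
    by_user_msgs = cohort.messages_by_user()
    by_user_usage = cohort.usage_by_user()

    behavior = behavior_feature_frame(cohort.users, by_user_msgs,
                                      by_user_usage, observation_days)
    appcats = app_feature_frame(cohort.users, by_user_usage, cat_map,
                                observation_days)
    senti_rows = {
        u.user_id: sentiment_proportions(by_user_msgs.get(u.user_id, []),
                                         sentiment_lexicon,
                                         u.reference_time)
        for u in cohort.users}
    sentiment = pd.DataFrame.from_dict(senti_rows, orient="index")

    docs = build_documents(cohort.messages)
    # users without messages still need a (zero) row
    for u in cohort.users:
        docs.setdefault(u.user_id, [])
    if any(docs.values()) and len(docs) >= 2:
        full_tfidf = TfidfModel(min_count=1).fit(list(docs.values()))
        ruliwc = lexicon_category_features(docs, category_lexicon, full_tfidf)
    else:
        from .text import CATEGORY_TAGS
        ruliwc = pd.DataFrame(
            np.zeros((len(cohort.users), 8)),
            index=[u.user_id for u in cohort.users],
            columns=[f"{c}_RuLIWC" for c in CATEGORY_TAGS])
    order = [u.user_id for u in cohort.users]
    return pd.concat([behavior.loc[order], appcats.loc[order],
                      sentiment.loc[order], ruliwc.loc[order]], axis=1)
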