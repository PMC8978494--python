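"""Linguistic feature families built from private-message lemma streams.

Three families are produced:

* **Sentiment proportions** — the l1-normalized frequency of positive and
  negative lexicon words over three trailing windows (30 days, 365 days,
  the whole history), six features per user.
* **Word features** — TfIDF scores (raw count x ln(N/df)) of frequent
  lemmas, pre-filtered on a disjoint heldout cohort by the p-value of the
  univariate regression F-test against each normalized scale (alpha 0.01);
  the union of the per-scale selections is the modeling vocabulary.
* **Category features** — per-user sums of TfIDF scores over the lemmas of
  each of eight closed-vocabulary categories (Bio, Cognitive, Social, Time,
  Percept, Feel, Hear, See), with the document frequencies computed over
  the *unrestricted* vocabulary.

Tokenization/lemmatization is a pluggable upstream contract: message
``tokens`` are assumed to already be lemmas.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import f_regression
from sklearn.utils.validation import check_is_fitted

from .records import MessageEvent

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "SENTIMENT_TAGS",
    "CATEGORY_TAGS",
    "SENTIMENT_FEATURES",
    "sentiment_proportions",
    "build_documents",
    "TfidfModel",
    "AnovaWordSelector",
    "anova_select_words",
    "lexicon_category_features",
]

SENTIMENT_TAGS = ("positive", "negative")
CATEGORY_TAGS = ("Bio", "Cognitive", "Social", "Time",
                 "Percept", "Feel", "Hear", "See")
#: window label -> trailing length in days (None = entire history)
SENTIMENT_WINDOWS = (("month", 30), ("year", 365), ("all", None))
SENTIMENT_FEATURES = tuple(
    f"{pol.capitalize()}_{win}" for win, _ in SENTIMENT_WINDOWS
    for pol in SENTIMENT_TAGS
)


@dataclass
class Lexicon:
    """A lemma -> tag mapping (sentiment polarity or word category)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lemmas_with_tag(self, tag: str) -> list[str]:
        return [w for w, t in self.entries.items() if t == tag]

    @classmethod
    def from_tsv(cls, path) -> "Lexicon":
        df = pd.read_csv(path, sep="\t", header=None, names=["lemma", "tag"],
                         dtype=str, comment="#")
        if df["lemma"].duplicated().any():
            raise ValueError("duplicate lemmas in lexicon")
        return cls(dict(zip(df["lemma"], df["tag"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"lemma": list(self.entries), "tag": list(self.entries.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


def sentiment_proportions(messages: Sequence[MessageEvent], lexicon: Lexicon,
                          reference_time: pd.Timestamp) -> dict[str, float]:
    """Six sentiment-proportion features for one user.

    For each window x polarity: (polarity-token count) / (total token count
    in the window); a window without tokens yields 0 for both polarities.
    """
    tags = set(lexicon.entries.values())
    if not set(SENTIMENT_TAGS) <= tags:
        raise ValueError("lexicon must contain both sentiment polarities")
    out: dict[str, float] = {}
    for win, days in SENTIMENT_WINDOWS:
        start = (reference_time - pd.Timedelta(days=days)
                 if days is not None else None)
        total = 0
        pol_counts = {t: 0 for t in SENTIMENT_TAGS}
        for msg in messages:
            if start is not None and msg.timestamp < start:
                continue
            total += len(msg.tokens)
            for tok in msg.tokens:
                tag = lexicon.entries.get(tok)
                if tag in pol_counts:
                    pol_counts[tag] += 1
        for pol in SENTIMENT_TAGS:
            name = f"{pol.capitalize()}_{win}"
            out[name] = pol_counts[pol] / total if total else 0.0
    return out


def build_documents(messages: Sequence[MessageEvent]) -> dict[str, list[str]]:
    """Concatenate each user's messages into one lemma document."""
    docs: dict[str, list[str]] = {}
    for msg in messages:
        docs.setdefault(msg.user_id, []).extend(msg.tokens)
    return docs


class TfidfModel(TransformerMixin, BaseEstimator):
    """TfIDF encoder over lemma documents: ``count(w, d) * ln(N / df(w))``.

    The vocabulary keeps lemmas with corpus frequency >= ``min_count``
    (default 200, matching the frequent-word floor used for the word
    features).  No length normalization is applied; the variant is isolated
    here so it can be swapped.

    Parameters
    ----------
    min_count : int
        Minimum total corpus frequency for a lemma to enter the vocabulary.
        Use 1 for an unrestricted vocabulary (category features).
    """

    def __init__(self, min_count: int = 200):
        self.min_count = min_count

    def fit(self, documents: Sequence[Sequence[str]], y=None) -> "TfidfModel":
        documents = list(documents)
        if len(documents) < 2:
            raise ValueError("need at least 2 documents")
        corpus_counts: Counter = Counter()
        df_counts: Counter = Counter()
        for doc in documents:
            c = Counter(doc)
            corpus_counts.update(c)
            df_counts.update(c.keys())
        vocab = sorted(w for w, c in corpus_counts.items()
                       if c >= self.min_count)
        if not vocab:
            raise ValueError(
                f"min_count={self.min_count} filtering left no vocabulary")
        self.vocabulary_ = vocab
        self.vocabulary_index_ = {w: i for i, w in enumerate(vocab)}
        self.n_documents_ = len(documents)
        self.df_ = np.array([df_counts[w] for w in vocab], dtype=float)
        self.idf_ = np.log(self.n_documents_ / self.df_)
        self.corpus_frequency_ = np.array(
            [corpus_counts[w] for w in vocab], dtype=float)
        return self

    def transform(self, documents: Sequence[Sequence[str]]) -> np.ndarray:
        check_is_fitted(self, "vocabulary_")
        X = np.zeros((len(documents), len(self.vocabulary_)))
        index = self.vocabulary_index_
        for i, doc in enumerate(documents):
            for w, c in Counter(doc).items():
                j = index.get(w)
                if j is not None:
                    X[i, j] = c
        return X * self.idf_

    def transform_frame(self, documents: Mapping[str, Sequence[str]]
                        ) -> pd.DataFrame:
        users = list(documents)
        X = self.transform([documents[u] for u in users])
        return pd.DataFrame(X, index=users, columns=self.vocabulary_)


class AnovaWordSelector(BaseEstimator):
    """Select words by the F-test of a univariate linear fit per target.

    For every word column and every target, the p-value of the simple
    linear regression of the target on the word's TfIDF score is computed
    (equivalent to the Pearson-correlation test); words with
    ``p <= alpha`` for a target are selected for it.  The union of the
    per-target selections forms the modeling vocabulary.  Constant columns
    are excluded with a logged note.
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, targets: Mapping[str, Sequence[float]],
            feature_names: Sequence[str] | None = None
            ) -> "AnovaWordSelector":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (users x words)")
        n, m = X.shape
        if feature_names is None:
            feature_names = [f"w{j}" for j in range(m)]
        self.feature_names_ = list(feature_names)
        variances = X.var(axis=0)
        nonconstant = variances > 0
        n_dropped = int(m - nonconstant.sum())
        if n_dropped:
            logger.info("excluding %d zero-variance word column(s)", n_dropped)
        self.pvalues_ = {}
        self.support_ = {}
        for name, y in targets.items():
            y = np.asarray(y, dtype=float)
            pvals = np.full(m, np.nan)
            if nonconstant.any() and np.var(y) > 0:
                _, p = f_regression(X[:, nonconstant], y)
                pvals[nonconstant] = p
            self.pvalues_[name] = pvals
            self.support_[name] = np.nan_to_num(pvals, nan=1.0) <= self.alpha
        if self.support_:
            self.union_support_ = np.logical_or.reduce(
                list(self.support_.values()))
        else:
            self.union_support_ = np.zeros(m, dtype=bool)
        return self

    def selected(self, target: str | None = None) -> list[str]:
        check_is_fitted(self, "union_support_")
        mask = (self.union_support_ if target is None
                else self.support_[target])
        return [w for w, keep in zip(self.feature_names_, mask) if keep]

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "union_support_")
        return np.asarray(X, dtype=float)[:, self.union_support_]


def anova_select_words(X, targets: Mapping[str, Sequence[float]],
                       feature_names: Sequence[str],
                       alpha: float = 0.01) -> dict[str, list[str]]:
    """Functional wrapper over :class:`AnovaWordSelector`.

    Returns per-target selected lemma lists plus their ``"union"``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return {**{t: [] for t in targets}, "union": []}
    sel = AnovaWordSelector(alpha=alpha).fit(X, targets, feature_names)
    out = {t: sel.selected(t) for t in targets}
    out["union"] = sel.selected(None)
    return out


def lexicon_category_features(documents: Mapping[str, Sequence[str]],
                              lexicon: Lexicon,
                              tfidf: TfidfModel | None = None) -> pd.DataFrame:
    """Eight closed-vocabulary category features per user.

    Each feature is the sum of the user's TfIDF scores over the lemmas of
    one category.  Words are counted regardless of frequency, so the TfIDF
    model must cover the unrestricted vocabulary (``min_count=1``); one is
    fitted on ``documents`` when not supplied.
    """
    users = list(documents)
    if tfidf is None:
        tfidf = TfidfModel(min_count=1).fit([documents[u] for u in users])
    X = tfidf.transform([documents[u] for u in users])
    vocab_index = tfidf.vocabulary_index_
    out = np.zeros((len(users), len(CATEGORY_TAGS)))
    for k, cat in enumerate(CATEGORY_TAGS):
        cols = [vocab_index[w] for w in lexicon.lemmas_with_tag(cat)
                if w in vocab_index]
        if cols:
            out[:, k] = X[:, cols].sum(axis=1)
    names = [f"{cat}_RuLIWC" for cat in CATEGORY_TAGS]
    return pd.DataFrame(out, index=users, columns=names)
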