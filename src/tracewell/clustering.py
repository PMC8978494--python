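"""Supervision-regularized consensus word clustering.

Frequent lemmas are clustered by spherical (cosine-distance) k-means over
word embeddings.  Because k-means is stochastic, a reproducible solution is
assembled in three steps:

1. **Regularized runs** — ten random restarts per regularization weight.
   Each run minimizes ``J = cosine inertia + weight * penalty`` where the
   *supervision penalty* is the sum over clusters of the two-sided p-value
   of the Pearson correlation between the cluster's per-user TfIDF-sum
   feature and the target scale.  J is evaluated after every Lloyd
   iteration and the argmin-J iterate is returned: the penalty steers the
   choice among iterates, not the assignment rule.
2. **Consensus** — per weight, the ten runs are fused through the
   co-association matrix: lemma pairs co-assigned in at least a threshold
   fraction of runs are linked, and consensus clusters are the connected
   components of the link graph.  Five thresholds per weight give the
   default 4 x 5 = 20 consensus solutions.
3. **Augmentation** — each solution is paired with a twin in which every
   infrequent lemma (below the frequency floor but covered by the
   embedding) joins the cluster whose centroid (mean member vector) is
   most cosine-similar.

The best candidate is selected on a disjoint heldout cohort: clusters
whose features correlate with the target at p < 0.05 are kept, and
candidates are ranked by the mean test MAE of a 10-fold random-forest
regression with recursive feature elimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import KFold
from sklearn.utils import check_random_state

logger = logging.getLogger(__name__)

__all__ = [
    "WordEmbeddings",
    "blob_embeddings",
    "ClusterSolution",
    "cluster_feature_matrix",
    "pearson_pvalues",
    "supervision_penalty",
    "RegularizedSphericalKMeans",
    "regularized_kmeans",
    "consensus_solution",
    "augment_infrequent",
    "sweep_solutions",
    "select_best_solution",
    "DEFAULT_WEIGHTS",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_WEIGHTS = (0, 50, 100, 500)
DEFAULT_THRESHOLDS = (0.25, 0.45, 0.65, 0.75, 0.85)


class WordEmbeddings:
    """Deterministic lemma -> fixed-dimension vector lookup.

    Zero vectors are rejected at load so cosine distances stay defined.
    """

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError("all vectors must share one 1-D shape")
        self._vectors = {w: np.asarray(v, dtype=float)
                         for w, v in vectors.items()}
        for w, v in self._vectors.items():
            if not np.linalg.norm(v) > 0:
                raise ValueError(f"zero vector for lemma {w!r}")
        self.dim = next(iter(dims))[0]

    def __contains__(self, lemma: str) -> bool:
        return lemma in self._vectors

    def __getitem__(self, lemma: str) -> np.ndarray:
        return self._vectors[lemma]

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def lemmas(self) -> list[str]:
        return list(self._vectors)

    def coverage(self, lemmas) -> dict[str, list[str]]:
        """Split lemmas into covered and out-of-vocabulary."""
        covered = [w for w in lemmas if w in self._vectors]
        oov = [w for w in lemmas if w not in self._vectors]
        return {"covered": covered, "oov": oov}

    def matrix(self, lemmas, unit: bool = True) -> np.ndarray:
        M = np.stack([self._vectors[w] for w in lemmas])
        if unit:
            M = M / np.linalg.norm(M, axis=1, keepdims=True)
        return M

    @classmethod
    def random(cls, lemmas, dim: int = 300, seed: int = 0) -> "WordEmbeddings":
        """Isotropic Gaussian vectors; deterministic in ``seed``."""
        rng = np.random.default_rng(seed)
        return cls({w: rng.normal(size=dim) for w in lemmas})

    @classmethod
    def from_word2vec_text(cls, path) -> "WordEmbeddings":
        """Read the plain-text word2vec format (`n dim` header line)."""
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("malformed word2vec text header")
            n, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"bad vector line for {parts[0]!r}")
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
        if len(vectors) != n:
            raise ValueError(f"header announced {n} vectors, read {len(vectors)}")
        return cls(vectors)

    def to_word2vec_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self._vectors)} {self.dim}\n")
            for w, v in self._vectors.items():
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in v) + "\n")


def blob_embeddings(lemmas, n_blobs: int, dim: int = 50, seed: int = 0,
                    noise: float = 0.05) -> tuple[WordEmbeddings, np.ndarray]:
    """Embeddings with planted well-separated blobs, for recovery tests.

    Lemma ``i`` belongs to blob ``i mod n_blobs``; returns the embeddings
    and the planted blob labels.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_blobs, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    labels = np.arange(len(lemmas)) % n_blobs
    vecs = {w: centers[labels[i]] + noise * rng.normal(size=dim)
            for i, w in enumerate(lemmas)}
    return WordEmbeddings(vecs), labels


@dataclass
class ClusterSolution:
    """A partition of a vocabulary into clusters plus generation metadata."""

    partition: dict[str, int]
    k: int
    weight: float
    threshold: float | None = None
    augmented: bool = False
    objective: float | None = None

    def __post_init__(self) -> None:
        # normalize ids to dense 0..C-1 (order of sorted original ids)
        ids = sorted(set(self.partition.values()))
        if ids and ids != list(range(len(ids))):
            remap = {c: i for i, c in enumerate(ids)}
            self.partition = {w: remap[c] for w, c in self.partition.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def labels(self, lemmas) -> np.ndarray:
        return np.array([self.partition[w] for w in lemmas])

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for w, c in self.partition.items():
            out.setdefault(c, []).append(w)
        return out


def cluster_feature_matrix(labels: np.ndarray, X: np.ndarray,
                           n_clusters: int | None = None) -> np.ndarray:
    """Per-user cluster features: sums of member-word TfIDF columns.

    ``X`` is users x words, column-aligned with ``labels``.
    """
    labels = np.asarray(labels)
    C = n_clusters if n_clusters is not None else int(labels.max()) + 1
    ind = sparse.csr_matrix(
        (np.ones(labels.size), (np.arange(labels.size), labels)),
        shape=(labels.size, C))
    return np.asarray(X @ ind.todense())


def pearson_pvalues(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Pearson-correlation p-value per column of ``F``.

    Zero-variance columns (or a zero-variance target) get p = 1.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    n = F.shape[0]
    p = np.ones(F.shape[1])
    sy = y.std()
    if n < 3 or sy == 0:
        return p
    Fc = F - F.mean(axis=0)
    sx = F.std(axis=0)
    ok = sx > 0
    r = (Fc[:, ok] * (y - y.mean())[:, None]).mean(axis=0) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r ** 2))
    p[ok] = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return p


def supervision_penalty(labels: np.ndarray, X: np.ndarray,
                        y: np.ndarray) -> float:
    """Sum over clusters of the p-value of the cluster-feature/target
    correlation; bounded by the number of clusters."""
    F = cluster_feature_matrix(labels, X)
    return float(pearson_pvalues(F, y).sum())


class RegularizedSphericalKMeans(BaseEstimator):
    """Spherical k-means with a supervision-penalized objective.

    Lloyd iterations run on unit-normalized vectors with cosine distance
    (``1 - cosine similarity``).  After each iteration the objective
    ``J = inertia + weight * penalty`` is evaluated and the argmin-J
    iterate is kept as the fitted solution, so with ``weight=0`` the
    estimator reduces to standard spherical k-means.

    Parameters
    ----------
    n_clusters : int
        Target cluster count (words, default 300).  When it is not below
        the vocabulary size every word becomes its own cluster.
    weight : float
        Regularization weight multiplying the supervision penalty.
    supervision : tuple (X, y), optional
        Users x words TfIDF matrix (column-aligned with the fitted
        vocabulary order) and target values.  Required when ``weight > 0``.
    max_iter : int
    random_state : int or RandomState

    Attributes
    ----------
    labels_ : ndarray of cluster ids (dense, 0..C-1)
    objective_ : float, J of the retained iterate
    inertia_ : float, cosine inertia of the retained iterate
    n_iter_ : number of Lloyd iterations executed
    """

    def __init__(self, n_clusters: int = 300, weight: float = 0.0,
                 supervision=None, max_iter: int = 30, random_state=None):
        self.n_clusters = n_clusters
        self.weight = weight
        self.supervision = supervision
        self.max_iter = max_iter
        self.random_state = random_state

    def _objective(self, inertia: float, labels: np.ndarray) -> float:
        if self.weight == 0 or self.supervision is None:
            if self.weight != 0 and self.supervision is None:
                raise ValueError("weight > 0 requires supervision=(X, y)")
            return inertia
        X, y = self.supervision
        return inertia + self.weight * supervision_penalty(labels, X, y)

    def fit(self, V, y=None) -> "RegularizedSphericalKMeans":
        V = np.asarray(V, dtype=float)
        if V.ndim != 2:
            raise ValueError("V must be words x dim")
        n = V.shape[0]
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero embedding vector")
        Vn = V / norms
        rng = check_random_state(self.random_state)
        if self.weight != 0 and self.supervision is None:
            raise ValueError("weight > 0 requires supervision=(X, y)")

        if self.n_clusters >= n:
            # degenerate regime: singletons, zero inertia
            self.labels_ = np.arange(n)
            self.inertia_ = 0.0
            self.objective_ = self._objective(0.0, self.labels_)
            self.n_iter_ = 0
            return self

        k = self.n_clusters
        centroids = Vn[rng.choice(n, size=k, replace=False)]
        best_obj = np.inf
        best = None
        labels = np.zeros(n, dtype=int)
        for it in range(self.max_iter):
            sim = Vn @ centroids.T
            new_labels = np.argmax(sim, axis=1)
            # re-seed empty clusters with the worst-fit points
            counts = np.bincount(new_labels, minlength=k)
            empties = np.flatnonzero(counts == 0)
            if empties.size:
                worst = np.argsort(sim[np.arange(n), new_labels])[:empties.size]
                for c, i in zip(empties, worst):
                    new_labels[i] = c
            inertia = float(np.sum(1.0 - sim[np.arange(n), new_labels]))
            obj = self._objective(inertia, new_labels)
            if obj < best_obj:
                best_obj = obj
                best = (new_labels.copy(), inertia)
            converged = it > 0 and np.array_equal(new_labels, labels)
            labels = new_labels
            # centroid update: normalized mean of members
            centroids = np.zeros_like(centroids)
            np.add.at(centroids, labels, Vn)
            cnorm = np.linalg.norm(centroids, axis=1, keepdims=True)
            cnorm[cnorm == 0] = 1.0
            centroids /= cnorm
            if converged:
                break
        raw_labels, inertia = best
        # densify cluster ids
        _, dense = np.unique(raw_labels, return_inverse=True)
        self.labels_ = dense
        self.inertia_ = inertia
        self.objective_ = float(best_obj)
        self.n_iter_ = it + 1
        return self


def regularized_kmeans(embeddings: WordEmbeddings, vocab, k: int,
                       weight: float = 0.0, tfidf=None, target=None,
                       random_state=None, max_iter: int = 30
                       ) -> ClusterSolution:
    """Run one penalized spherical k-means over ``vocab`` and wrap the
    result as a :class:`ClusterSolution`."""
    vocab = list(vocab)
    missing = [w for w in vocab if w not in embeddings]
    if missing:
        raise ValueError(f"{len(missing)} lemma(s) lack embeddings, "
                         f"e.g. {missing[:3]}")
    supervision = None
    if weight != 0:
        if tfidf is None or target is None:
            raise ValueError("weight > 0 requires tfidf and target")
        supervision = (np.asarray(tfidf, float), np.asarray(target, float))
    est = RegularizedSphericalKMeans(
        n_clusters=k, weight=weight, supervision=supervision,
        max_iter=max_iter, random_state=random_state,
    ).fit(embeddings.matrix(vocab))
    return ClusterSolution(
        partition=dict(zip(vocab, (int(c) for c in est.labels_))),
        k=k, weight=weight, objective=est.objective_)


def consensus_solution(runs, threshold: float) -> ClusterSolution:
    """Fuse runs via the co-association graph at the given threshold.

    Lemma pairs whose co-assignment fraction across runs is >= threshold
    are linked; consensus clusters are the connected components.  A
    threshold above 1 therefore yields all singletons.
    """
    if not runs:
        raise ValueError("no runs to fuse")
    vocab = list(runs[0].partition)
    vocab_set = set(vocab)
    for r in runs:
        if set(r.partition) != vocab_set:
            raise ValueError("all runs must partition the same vocabulary")
    n = len(vocab)
    co = np.zeros((n, n))
    for r in runs:
        labels = r.labels(vocab)
        onehot = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), labels)),
            shape=(n, labels.max() + 1))
        co += np.asarray((onehot @ onehot.T).todense())
    co /= len(runs)
    adj = sparse.csr_matrix(co >= threshold)
    n_comp, comp = connected_components(adj, directed=False)
    return ClusterSolution(
        partition=dict(zip(vocab, (int(c) for c in comp))),
        k=runs[0].k, weight=runs[0].weight, threshold=threshold)


def augment_infrequent(solution: ClusterSolution, infrequent,
                       embeddings: WordEmbeddings) -> ClusterSolution:
    """Twin solution with infrequent lemmas joined to their closest cluster.

    Closeness is cosine similarity to the cluster centroid (mean member
    vector); original memberships are unchanged.  Lemmas without embedding
    coverage are skipped with a logged note.
    """
    partition = dict(solution.partition)
    members = solution.members()
    centroids = {}
    for c, lemmas in members.items():
        covered = [w for w in lemmas if w in embeddings]
        if covered:
            centroids[c] = embeddings.matrix(covered).mean(axis=0)
    if not centroids:
        raise ValueError("no cluster has embedding coverage")
    ids = sorted(centroids)
    C = np.stack([centroids[c] for c in ids])
    C = C / np.linalg.norm(C, axis=1, keepdims=True)
    for w in infrequent:
        if w in partition:
            continue
        if w not in embeddings:
            logger.info("infrequent lemma %r lacks an embedding; skipped", w)
            continue
        v = embeddings[w]
        v = v / np.linalg.norm(v)
        partition[w] = ids[int(np.argmax(C @ v))]
    return replace(solution, partition=partition, augmented=True)


def sweep_solutions(embeddings: WordEmbeddings, vocab, tfidf, target,
                    k: int = 300, weights=DEFAULT_WEIGHTS,
                    thresholds=DEFAULT_THRESHOLDS, n_runs: int = 10,
                    infrequent=None, random_state: int = 0,
                    max_iter: int = 30) -> list[ClusterSolution]:
    """Full candidate sweep: |weights| x |thresholds| consensus solutions,
    each paired with an infrequent-word-augmented twin (40 at defaults)."""
    rng = np.random.default_rng(random_state)
    candidates: list[ClusterSolution] = []
    for w in weights:
        seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
        runs = [regularized_kmeans(embeddings, vocab, k=k, weight=w,
                                   tfidf=tfidf, target=target,
                                   random_state=int(s), max_iter=max_iter)
                for s in seeds]
        for t in thresholds:
            cons = consensus_solution(runs, t)
            candidates.append(cons)
            candidates.append(
                augment_infrequent(cons, infrequent or [], embeddings))
    return candidates


def select_best_solution(candidates, X_heldout, vocab, y_heldout,
                         n_folds: int = 10, p_threshold: float = 0.05,
                         n_estimators: int = 60, random_state: int = 0
                         ) -> tuple[ClusterSolution, pd.DataFrame]:
    """Rank candidates on the heldout cohort and return the MAE argmin.

    For each candidate: keep clusters whose TfIDF-sum feature correlates
    with the target at ``p < p_threshold``; run a 10-fold random-forest
    regression with recursive feature elimination (importance-ranked, 10%
    per step, down to half the features) and record the mean test MAE.  A
    candidate with no surviving clusters gets the worst possible MAE.

    Returns the winning solution and a metadata table with one row per
    candidate: regularization weight, consensus threshold, augmented flag,
    number of (surviving) clusters, MAE.
    """
    if not candidates:
        raise ValueError("no candidate solutions")
    X = np.asarray(X_heldout, dtype=float)
    y = np.asarray(y_heldout, dtype=float)
    vocab = list(vocab)
    col = {w: j for j, w in enumerate(vocab)}
    rows = []
    maes = []
    for cand in candidates:
        # restrict the partition to the heldout vocabulary
        keep = [(w, c) for w, c in cand.partition.items() if w in col]
        labels = np.array([c for _, c in keep])
        cols = np.array([col[w] for w, _ in keep])
        _, labels = np.unique(labels, return_inverse=True)
        F = cluster_feature_matrix(labels, X[:, cols])
        pvals = pearson_pvalues(F, y)
        surviving = pvals < p_threshold
        n_surv = int(surviving.sum())
        if n_surv == 0:
            logger.info("candidate (w=%s, t=%s, aug=%s) has no surviving "
                        "clusters; worst MAE assigned",
                        cand.weight, cand.threshold, cand.augmented)
            mae = np.inf
        else:
            Fs = F[:, surviving]
            fold_maes = []
            kf = KFold(n_splits=n_folds, shuffle=True,
                       random_state=random_state)
            for tr, te in kf.split(Fs):
                rf = RandomForestRegressor(n_estimators=n_estimators,
                                           random_state=random_state)
                n_feat = Fs.shape[1]
                if n_feat > 1:
                    rfe = RFE(rf, n_features_to_select=max(1, n_feat // 2),
                              step=0.1)
                    rfe.fit(Fs[tr], y[tr])
                    pred = rfe.predict(Fs[te])
                else:
                    rf.fit(Fs[tr], y[tr])
                    pred = rf.predict(Fs[te])
                fold_maes.append(mean_absolute_error(y[te], pred))
            mae = float(np.mean(fold_maes))
        maes.append(mae)
        rows.append({
            "regularization_weight": cand.weight,
            "consensus_threshold": cand.threshold,
            "infrequent_words": cand.augmented,
            "n_clusters": n_surv,
            "mae": mae,
        })
    table = pd.DataFrame(rows)
    best = int(np.argmin(maes))
    return candidates[best], table
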