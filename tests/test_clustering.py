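import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tracewell.clustering import (ClusterSolution, RegularizedSphericalKMeans,
                                  WordEmbeddings, augment_infrequent,
                                  blob_embeddings, cluster_feature_matrix,
                                  consensus_solution, pearson_pvalues,
                                  regularized_kmeans, select_best_solution,
                                  supervision_penalty, sweep_solutions)


def brute_force_components(vocab, co, threshold):
    """Exhaustive graph search oracle for consensus components."""
    n = len(vocab)
    adj = {i: {j for j in range(n) if co[i, j] >= threshold}
           for i in range(n)}
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestSupervisionPenalty:
    def test_perfectly_correlated_cluster_contributes_near_zero(self, rng):
        X = rng.normal(size=(100, 4))
        y = X[:, 0] + X[:, 1]  # cluster 0 = {0, 1} sums to y exactly
        labels = np.array([0, 0, 1, 1])
        penalty = supervision_penalty(labels, X, y)
        # cluster 0's p-value ~ 0; cluster 1's is at most 1
        assert penalty < 1.05

    def test_bounded_by_number_of_clusters(self, rng):
        X = rng.normal(size=(50, 10))
        labels = np.arange(10) % 4
        assert 0 <= supervision_penalty(labels, X, rng.normal(size=50)) <= 4

    def test_null_clusters_average_half(self, rng):
        # independent features: p-values uniform, mean penalty ~ 0.5 * C
        C, reps = 20, 40
        vals = []
        for _ in range(reps):
            X = rng.normal(size=(200, C))
            vals.append(supervision_penalty(np.arange(C), X,
                                            rng.normal(size=200)))
        assert np.mean(vals) / C == pytest.approx(0.5, abs=0.08)

    def test_zero_variance_cluster_counts_as_one(self):
        X = np.zeros((30, 2))
        y = np.arange(30.0)
        assert supervision_penalty(np.array([0, 1]), X, y) == 2.0


class TestRegularizedKMeans:
    def test_weight_zero_reduces_to_cosine_inertia(self, rng):
        V = rng.normal(size=(60, 8))
        est = RegularizedSphericalKMeans(n_clusters=5, random_state=0).fit(V)
        assert est.objective_ == est.inertia_
        Vn = V / np.linalg.norm(V, axis=1, keepdims=True)
        # recompute inertia against the retained labels' centroids
        centroids = np.stack([
            Vn[est.labels_ == c].mean(axis=0)
            / np.linalg.norm(Vn[est.labels_ == c].mean(axis=0))
            for c in range(est.labels_.max() + 1)])
        manual = np.sum(1 - np.einsum("ij,ij->i", Vn,
                                      centroids[est.labels_]))
        # retained iterate's inertia can differ from the post-update one,
        # but both are valid cosine inertias of the same partition scale
        assert est.inertia_ == pytest.approx(manual, rel=0.2)

    def test_k_at_least_vocabulary_gives_singletons(self, rng):
        V = rng.normal(size=(7, 4))
        est = RegularizedSphericalKMeans(n_clusters=10).fit(V)
        assert sorted(est.labels_) == list(range(7))
        assert est.inertia_ == 0.0

    def test_weight_without_supervision_rejected(self, rng):
        with pytest.raises(ValueError):
            RegularizedSphericalKMeans(n_clusters=2, weight=10.0).fit(
                rng.normal(size=(10, 3)))

    def test_planted_blobs_recovered(self):
        lemmas = [f"b{i}" for i in range(40)]
        emb, planted = blob_embeddings(lemmas, 2, dim=10, seed=3)
        wins = 0
        for seed in range(100):
            sol = regularized_kmeans(emb, lemmas, k=2, random_state=seed)
            if adjusted_rand_score(planted, sol.labels(lemmas)) == 1.0:
                wins += 1
        assert wins >= 95

    def test_deterministic_in_random_state(self, rng):
        V = rng.normal(size=(30, 6))
        a = RegularizedSphericalKMeans(n_clusters=4, random_state=7).fit(V)
        b = RegularizedSphericalKMeans(n_clusters=4, random_state=7).fit(V)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_supervision_weight_prefers_correlated_iterates(self, rng):
        # smoke: with weight > 0 the objective includes the penalty term
        V = rng.normal(size=(20, 5))
        X = rng.normal(size=(50, 20))
        y = rng.normal(size=50)
        est = RegularizedSphericalKMeans(
            n_clusters=3, weight=50.0, supervision=(X, y),
            random_state=0).fit(V)
        assert est.objective_ >= est.inertia_


class TestConsensus:
    def make_solution(self, labels, vocab):
        return ClusterSolution(dict(zip(vocab, labels)), k=3, weight=0)

    def test_identical_runs_reproduce_the_partition(self):
        vocab = list("abcde")
        runs = [self.make_solution([0, 0, 1, 1, 2], vocab)] * 10
        for t in (0.25, 0.85, 1.0):
            cons = consensus_solution(runs, t)
            assert (cons.labels(vocab)[:2] == cons.labels(vocab)[0]).all()
            assert cons.n_clusters == 3

    def test_threshold_above_one_gives_singletons(self):
        vocab = list("abcd")
        runs = [self.make_solution([0, 0, 0, 0], vocab)] * 10
        cons = consensus_solution(runs, 1.5)
        assert cons.n_clusters == 4

    def test_matches_brute_force_components(self, rng):
        vocab = [f"w{i}" for i in range(5)]
        runs = [self.make_solution(rng.integers(0, 3, size=5), vocab)
                for _ in range(10)]
        n = 5
        co = np.zeros((n, n))
        for r in runs:
            lab = r.labels(vocab)
            for i, j in itertools.product(range(n), repeat=2):
                co[i, j] += lab[i] == lab[j]
        co /= len(runs)
        for threshold in (0.25, 0.45, 0.65):
            cons = consensus_solution(runs, threshold)
            got = {frozenset(np.flatnonzero(cons.labels(vocab) == c))
                   for c in range(cons.n_clusters)}
            assert got == brute_force_components(vocab, co, threshold)

    def test_higher_threshold_refines(self, rng):
        vocab = [f"w{i}" for i in range(12)]
        runs = [self.make_solution(rng.integers(0, 4, size=12), vocab)
                for _ in range(10)]
        lo = consensus_solution(runs, 0.45).labels(vocab)
        hi = consensus_solution(runs, 0.75).labels(vocab)
        # every high-threshold cluster sits inside one low-threshold cluster
        for c in np.unique(hi):
            assert len(np.unique(lo[hi == c])) == 1


class TestAugmentation:
    def test_no_infrequent_words_only_flips_flag(self, rng):
        vocab = list("abc")
        emb = WordEmbeddings.random(vocab, dim=5, seed=0)
        sol = ClusterSolution(dict(zip(vocab, [0, 0, 1])), k=2, weight=0)
        aug = augment_infrequent(sol, [], emb)
        assert aug.augmented and not sol.augmented
        assert aug.partition == sol.partition

    def test_identical_vector_joins_that_cluster(self):
        vecs = {"a": np.array([1.0, 0.0]), "b": np.array([0.9, 0.1]),
                "c": np.array([0.0, 1.0]), "new": np.array([0.0, 1.0])}
        emb = WordEmbeddings(vecs)
        sol = ClusterSolution({"a": 0, "b": 0, "c": 1}, k=2, weight=0)
        aug = augment_infrequent(sol, ["new"], emb)
        assert aug.partition["new"] == 1

    def test_matches_exhaustive_similarity_oracle(self, rng):
        vocab = [f"w{i}" for i in range(9)]
        emb = WordEmbeddings.random(vocab + ["x1", "x2"], dim=6, seed=1)
        sol = ClusterSolution(dict(zip(vocab, np.arange(9) % 3)),
                              k=3, weight=0)
        aug = augment_infrequent(sol, ["x1", "x2"], emb)
        for w in ("x1", "x2"):
            v = emb[w] / np.linalg.norm(emb[w])
            sims = {}
            for c in range(3):
                members = [u for u, cc in sol.partition.items() if cc == c]
                centroid = emb.matrix(members).mean(axis=0)
                centroid /= np.linalg.norm(centroid)
                sims[c] = centroid @ v
            assert aug.partition[w] == max(sims, key=sims.get)

    def test_uncovered_lemma_skipped(self, rng):
        vocab = list("ab")
        emb = WordEmbeddings.random(vocab, dim=4, seed=0)
        sol = ClusterSolution({"a": 0, "b": 0}, k=1, weight=0)
        aug = augment_infrequent(sol, ["missing"], emb)
        assert "missing" not in aug.partition


class TestSweepAndSelection:
    def test_default_sweep_counts(self, rng):
        vocab = [f"w{i}" for i in range(30)]
        emb = WordEmbeddings.random(vocab, dim=8, seed=0)
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        cands = sweep_solutions(emb, vocab, X, y, k=4, n_runs=3,
                                random_state=0, max_iter=8)
        consensus = [c for c in cands if not c.augmented]
        assert len(consensus) == 20 and len(cands) == 40
        for c in cands:
            assert set(c.partition) == set(vocab)

    def test_single_weight_threshold_gives_one_pair(self, rng):
        vocab = [f"w{i}" for i in range(10)]
        emb = WordEmbeddings.random(vocab, dim=5, seed=0)
        cands = sweep_solutions(emb, vocab, None, None, k=3, weights=(0,),
                                thresholds=(0.5,), n_runs=2, random_state=0)
        assert len(cands) == 2
        assert cands[0].augmented is False and cands[1].augmented is True

    def test_single_candidate_returned_unconditionally(self, rng):
        vocab = list("abcd")
        sol = ClusterSolution(dict(zip(vocab, [0, 0, 1, 1])), k=2, weight=0)
        X = rng.normal(size=(40, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        best, table = select_best_solution([sol], X, vocab, y, n_folds=3,
                                           n_estimators=10)
        assert best is sol
        assert list(table.columns) == ["regularization_weight",
                                       "consensus_threshold",
                                       "infrequent_words", "n_clusters",
                                       "mae"]

    def test_planted_signal_candidate_beats_noise(self):
        # candidate A groups the signal words into one cluster feature;
        # candidate B partitions only target-independent noise words
        vocab = [f"s{i}" for i in range(12)] + [f"n{i}" for i in range(12)]
        signal = ClusterSolution(
            {w: (0 if i < 4 else 1 + i % 2)
             for i, w in enumerate(vocab[:12])}, k=3, weight=0)
        noise = ClusterSolution(
            {w: i % 3 for i, w in enumerate(vocab[12:])}, k=3, weight=0)
        wins = 0
        n_sims = 50
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(60, 24))
            y = X[:, :4].sum(axis=1) + rng.normal(0, 0.8, 60)
            best, _ = select_best_solution([signal, noise], X, vocab, y,
                                           n_folds=10, n_estimators=20,
                                           random_state=s)
            if best is signal:
                wins += 1
        assert wins >= int(0.9 * n_sims)


def test_cluster_feature_matrix_sums_member_columns(rng):
    X = rng.normal(size=(6, 5))
    labels = np.array([0, 0, 1, 2, 1])
    F = cluster_feature_matrix(labels, X)
    np.testing.assert_allclose(F[:, 0], X[:, [0, 1]].sum(axis=1))
    np.testing.assert_allclose(F[:, 1], X[:, [2, 4]].sum(axis=1))
    np.testing.assert_allclose(F[:, 2], X[:, 3])


def test_pearson_pvalues_match_scipy(rng):
    from scipy import stats
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    p = pearson_pvalues(X, y)
    for j in range(3):
        assert p[j] == pytest.approx(stats.pearsonr(X[:, j], y)[1])


def test_word2vec_text_round_trip(tmp_path, rng):
    emb = WordEmbeddings.random(["alpha", "beta"], dim=4, seed=2)
    path = tmp_path / "model.vec"
    emb.to_word2vec_text(path)
    back = WordEmbeddings.from_word2vec_text(path)
    assert back.dim == 4
    np.testing.assert_allclose(back["alpha"], emb["alpha"], rtol=1e-4)


def test_zero_vector_rejected():
    with pytest.raises(ValueError):
        WordEmbeddings({"a": np.zeros(3)})
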