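"""Metric tests against independent brute-force oracles and closed forms."""

import itertools

import numpy as np
import pytest

import cellbridge as cb

# ---------------------------------------------------------------------------
# brute-force oracles (no sklearn)


def oracle_ari(a, b):
    """Chance-adjusted Rand index from the contingency table, via direct
    evaluation of the pair-counting formula."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    if n < 2:
        return 1.0
    cats_a = sorted(set(a.tolist()))
    cats_b = sorted(set(b.tolist()))
    table = np.zeros((len(cats_a), len(cats_b)))
    for x, y in zip(a, b):
        table[cats_a.index(x), cats_b.index(y)] += 1

    def c2(x):
        return x * (x - 1) / 2

    sum_ij = c2(table).sum()
    sum_a = c2(table.sum(axis=1)).sum()
    sum_b = c2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / c2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions degenerate
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def oracle_nmi(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    cats_a = sorted(set(a.tolist()))
    cats_b = sorted(set(b.tolist()))

    def entropy(labels, cats):
        h = 0.0
        for c in cats:
            p = (labels == c).mean()
            if p > 0:
                h -= p * np.log(p)
        return h

    ha, hb = entropy(a, cats_a), entropy(b, cats_b)
    if ha == 0 or hb == 0:
        return 0.0
    mi = 0.0
    for ca in cats_a:
        for cbb in cats_b:
            pab = ((a == ca) & (b == cbb)).mean()
            if pab > 0:
                mi += pab * np.log(pab / ((a == ca).mean() * (b == cbb).mean()))
    return mi / np.sqrt(ha * hb)


def oracle_f1_macro(true, pred):
    true = np.asarray(true)
    pred = np.asarray(pred)
    scores = []
    for c in sorted(set(true.tolist()) | set(pred.tolist())):
        tp = ((true == c) & (pred == c)).sum()
        fp = ((true != c) & (pred == c)).sum()
        fn = ((true == c) & (pred != c)).sum()
        denom = 2 * tp + fp + fn
        scores.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(scores))


def oracle_overcorrection(coords, labels, k):
    """Direct per-cell scan with an explicit distance sort."""
    coords = np.asarray(coords)
    labels = np.asarray(labels)
    n = len(labels)
    bad = 0
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        d[i] = np.inf
        neigh = np.argsort(d, kind="stable")[:k]
        bad += (labels[neigh] != labels[i]).sum()
    return bad / (n * k)


def all_label_pairs(n, alphabet="ABC"):
    for a in itertools.product(alphabet, repeat=n):
        for b in itertools.product(alphabet, repeat=n):
            yield list(a), list(b)


# ---------------------------------------------------------------------------


class TestARI:
    def test_identical_partitions(self):
        assert cb.adjusted_rand_index(list("AABBCC"), list("XXYYZZ")) == 1.0

    def test_degenerate_adjustment(self):
        a = ["A"] * 4
        b = ["w", "x", "y", "z"]
        assert cb.adjusted_rand_index(a, b) == pytest.approx(0.0)

    def test_matches_oracle_on_small_vectors(self):
        for a, b in all_label_pairs(4):
            assert cb.adjusted_rand_index(a, b) == pytest.approx(
                oracle_ari(a, b), abs=1e-12
            ), (a, b)

    def test_aabb_vs_abab(self):
        val = cb.adjusted_rand_index(list("AABB"), list("ABAB"))
        assert val == pytest.approx(oracle_ari(list("AABB"), list("ABAB")))
        assert val == pytest.approx(-0.5)


class TestNMI:
    def test_identical(self):
        assert cb.normalized_mutual_information(list("AABB"), list("XXYY")) == 1.0

    def test_independent_design(self):
        a = list("AABB")
        b = list("ABAB")
        # 2x2 balanced independent design has zero mutual information
        a2 = ["A", "A", "B", "B"]
        b2 = ["X", "Y", "X", "Y"]
        assert cb.normalized_mutual_information(a2, b2) == pytest.approx(0.0, abs=1e-12)
        assert cb.normalized_mutual_information(a, b) == pytest.approx(
            oracle_nmi(a, b), abs=1e-12
        )

    def test_constant_partition_guard(self):
        with pytest.warns(UserWarning, match="zero entropy"):
            assert cb.normalized_mutual_information(["A"] * 4, list("ABAB")) == 0.0


class TestSymmetryAndRelabeling:
    @pytest.mark.parametrize("metric", [cb.adjusted_rand_index,
                                        cb.normalized_mutual_information])
    def test_symmetric_and_relabel_invariant(self, metric):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 3, size=30)
            assert metric(a, b) == pytest.approx(metric(b, a), abs=1e-12)
            perm = rng.permutation(3)
            assert metric(perm[a], b) == pytest.approx(metric(a, b), abs=1e-12)


class TestF1:
    def test_perfect(self):
        assert cb.f1_macro(list("ABAB"), list("ABAB")) == 1.0

    def test_balanced_errors(self):
        # per class: TP=1, FP=1, FN=1 -> F1 = 0.5 each -> macro 0.5
        true = ["A", "A", "B", "B"]
        pred = ["A", "B", "A", "B"]
        assert cb.f1_macro(true, pred) == pytest.approx(0.5)

    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(0, 3, size=40).astype(str)
            p = rng.integers(0, 3, size=40).astype(str)
            assert cb.f1_macro(t, p) == pytest.approx(oracle_f1_macro(t, p),
                                                      abs=1e-12)


class TestConfusionMatrix:
    def test_perfect_prediction_identity(self):
        C = cb.confusion_matrix(list("AABB"), list("AABB"))
        assert C.loc["A", "A"] == 100.0 and C.loc["B", "B"] == 100.0
        assert C.loc["A", "B"] == 0.0

    def test_half_split_row(self):
        C = cb.confusion_matrix(["A"] * 4, ["A", "A", "B", "B"])
        assert C.loc["A", "A"] == 50.0 and C.loc["A", "B"] == 50.0

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 4, size=100).astype(str)
        p = rng.integers(0, 4, size=100).astype(str)
        C = cb.confusion_matrix(t, p)
        np.testing.assert_allclose(C.sum(axis=1).values, 100.0, rtol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="aligned"):
            cb.confusion_matrix(["A"], ["A", "B"])


class TestSilhouette:
    def test_two_tight_far_clusters(self):
        # clusters at {0, 0.1} and {10, 10.1}: a = 0.1, b ~ 10 -> score ~ 0.99
        coords = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        labels = ["a", "a", "b", "b"]
        a = 0.1
        bs = [9.95, 10.05, 9.95, 10.05]
        expected = np.mean([(b - a) / b for b in bs])
        assert cb.silhouette_on_embedding(coords, labels) == pytest.approx(
            expected, rel=1e-10
        )

    def test_interleaved_clusters_near_zero(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(100, 2))
        labels = ["a", "b"] * 50
        assert cb.silhouette_on_embedding(coords, labels) < 0.1

    def test_identical_points_guard(self):
        coords = np.zeros((6, 2))
        assert cb.silhouette_on_embedding(coords, ["a", "b"] * 3) == 0.0


def islands(n_islands, per_island_by_batch, sep=1000.0, jitter=0.0, seed=0):
    """Well-separated islands with a fixed batch composition each."""
    rng = np.random.default_rng(seed)
    coords, batches = [], []
    for i in range(n_islands):
        center = np.array([i * sep, 0.0])
        for batch, m in per_island_by_batch.items():
            for _ in range(m):
                coords.append(center + rng.normal(0, jitter, 2))
                batches.append(batch)
    return np.asarray(coords), np.asarray(batches)


class TestBatchEntropyMixing:
    def test_perfect_mixing_extreme(self):
        """Islands of exactly 15+15 cells per batch force every 30-cell
        neighborhood to be perfectly mixed: raw = ln(1/2), rescaled = 1."""
        coords, batches = islands(4, {"b0": 15, "b1": 15})
        raw, rescaled = cb.batch_entropy_mixing(coords, batches, seed=0)
        assert raw == pytest.approx(np.log(0.5), abs=1e-6)
        assert rescaled == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_extreme(self):
        coords, batches = islands(2, {"b0": 40}, seed=1)
        coords2, batches2 = islands(2, {"b1": 40}, seed=2)
        coords2[:, 0] += 1e6
        raw, rescaled = cb.batch_entropy_mixing(
            np.vstack([coords, coords2]), np.concatenate([batches, batches2]),
            seed=0,
        )
        assert raw == pytest.approx(0.0, abs=1e-12)
        assert rescaled == pytest.approx(0.0, abs=1e-12)

    def test_imbalance_correction(self):
        """90/10 batches with i.i.d. mixed neighborhoods: the p/P correction
        yields a near-perfect score despite the imbalance."""
        rng = np.random.default_rng(4)
        coords = rng.random((1000, 2))
        batches = np.where(rng.random(1000) < 0.9, "big", "small")
        _, rescaled = cb.batch_entropy_mixing(
            coords, batches, n_probes=200, n_iterations=10, seed=0
        )
        assert rescaled > 0.85

    def test_mask_removing_batch_rejected(self):
        coords, batches = islands(2, {"b0": 15, "b1": 15})
        mask = batches == "b0"
        with pytest.raises(ValueError, match="whole batch"):
            cb.batch_entropy_mixing(coords, batches, common_mask=mask)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        coords = rng.random((200, 2))
        batches = np.array(["a", "b"] * 100)
        r1 = cb.batch_entropy_mixing(coords, batches, seed=3)
        r2 = cb.batch_entropy_mixing(coords, batches, seed=3)
        assert r1 == r2

    def test_monotone_under_interpolation(self):
        """Lerping an embedding from batch-separated to pooled increases the
        mixing score monotonically."""
        rng = np.random.default_rng(6)
        pooled = rng.normal(size=(200, 2))
        offset = np.where(np.arange(200) < 100, -50.0, 50.0)[:, None]
        batches = np.array(["a"] * 100 + ["b"] * 100)
        scores = []
        for t in np.linspace(0, 1, 5):
            coords = pooled + (1 - t) * offset
            _, rescaled = cb.batch_entropy_mixing(coords, batches, seed=0)
            scores.append(rescaled)
        assert all(s2 >= s1 - 1e-9 for s1, s2 in zip(scores, scores[1:]))


class TestLISI:
    def test_single_category_is_one(self):
        rng = np.random.default_rng(7)
        vals, mean = cb.lisi(rng.random((50, 2)), ["one"] * 50)
        np.testing.assert_allclose(vals, 1.0)

    def test_uniform_two_category_neighborhood_is_two(self):
        # coincident points with balanced labels: uniform weights, P = (1/2, 1/2)
        coords = np.zeros((12, 2))
        labels = ["a", "b"] * 6
        vals, mean = cb.lisi(coords, labels)
        np.testing.assert_allclose(vals, 2.0, atol=1e-6)

    def test_bounds(self):
        rng = np.random.default_rng(8)
        coords = rng.random((80, 2))
        labels = rng.integers(0, 3, size=80).astype(str)
        vals, _ = cb.lisi(coords, labels)
        assert (vals >= 1 - 1e-9).all() and (vals <= 3 + 1e-9).all()

    def test_matches_direct_implementation(self):
        """Independent dense implementation of the perplexity-calibrated
        Gaussian kernel on a small seeded dataset."""
        rng = np.random.default_rng(9)
        n = 50
        coords = rng.random((n, 2))
        labels = rng.integers(0, 2, size=n).astype(str)
        perplexity = 10

        k = min(3 * perplexity, n)
        vals_ref = []
        for i in range(n):
            d2 = ((coords - coords[i]) ** 2).sum(axis=1)
            order = np.argsort(d2, kind="stable")[:k]
            di = d2[order]
            lo, hi, beta = 0.0, None, 1.0 / di.mean()
            for _ in range(100):
                w = np.exp(-beta * di)
                w /= w.sum()
                H = -(w[w > 0] * np.log(w[w > 0])).sum()
                if abs(H - np.log(perplexity)) < 1e-12:
                    break
                if H > np.log(perplexity):
                    lo, beta = beta, (beta * 2 if hi is None else (beta + hi) / 2)
                else:
                    hi, beta = beta, (lo + beta) / 2
            P = np.array([w[labels[order] == c].sum() for c in sorted(set(labels))])
            vals_ref.append(1.0 / (P**2).sum())
        vals, _ = cb.lisi(coords, labels, perplexity=perplexity)
        np.testing.assert_allclose(vals, vals_ref, rtol=1e-6)


class TestOverCorrection:
    def test_pure_blobs_zero(self):
        coords, batches = islands(2, {"x": 20}, seed=10, jitter=0.1)
        labels = ["t0"] * 20 + ["t1"] * 20
        assert cb.over_correction_score(coords, labels, k=5) == 0.0

    def test_random_labels_half(self):
        rng = np.random.default_rng(11)
        coords = rng.random((400, 2))
        labels = rng.permutation(["a", "b"] * 200)
        score = cb.over_correction_score(coords, labels, k=100)
        assert score == pytest.approx(0.5, abs=0.05)

    def test_alternating_types_one(self):
        # two types at perfectly alternating positions, k=1: every nearest
        # neighbor differs
        coords = np.arange(20, dtype=float)[:, None]
        labels = ["a", "b"] * 10
        assert cb.over_correction_score(coords, labels, k=1) == 1.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        coords = rng.random((60, 3))
        labels = rng.integers(0, 3, size=60).astype(str)
        for k in (1, 5, 15):
            assert cb.over_correction_score(coords, labels, k=k) == pytest.approx(
                1.0 - (1.0 - oracle_overcorrection(coords, labels, k)), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(13)
        coords = rng.random((50, 2))
        labels = rng.integers(0, 2, size=50).astype(str)
        k = 7
        score = cb.over_correction_score(coords, labels, k=k)
        same_fraction = 1.0 - oracle_overcorrection(coords, labels, k)
        assert score + same_fraction == pytest.approx(1.0, abs=1e-12)

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="k="):
            cb.over_correction_score(np.zeros((5, 2)), ["a"] * 5, k=5)


def test_common_type_mask():
    batches = ["b0", "b0", "b1", "b1", "b1"]
    types = ["shared", "solo0", "shared", "solo1", "solo1"]
    mask = cb.common_type_mask(batches, types)
    assert mask.tolist() == [True, False, True, False, False]
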