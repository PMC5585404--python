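import numpy as np
import pytest

from convmine.cluster import cluster, distance_matrix, uncentered_correlation


def brute_force_average_linkage(d):
    """Agglomeration recomputing all cross-cluster mean distances from the
    original matrix at every step; ties to the smallest sorted cluster pair."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dd = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dd < best[0] - 1e-15:
                    best = (dd, a, b)
        dd, a, b = best
        merges.append((a, b, 1.0 - dd))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestUncenteredCorrelation:
    def test_identity(self):
        assert uncentered_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonality(self):
        assert uncentered_correlation([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_positive_scale_invariance(self):
        assert uncentered_correlation([1, 2], [2, 4]) == pytest.approx(1.0)

    def test_differs_from_centered_correlation(self):
        # constant offset changes the uncentered similarity (no mean removal)
        x, y = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        assert uncentered_correlation(x, y) < 1.0

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            uncentered_correlation([0, 0], [1, 2])


class TestDistanceMatrix:
    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        m = rng.normal(5, 2, size=(6, 4))
        d = distance_matrix(m)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 2 + 1e-12).all()


class TestCluster:
    def test_identical_rows_merge_first(self):
        m = np.array([[1.0, 2.0], [5.0, -1.0], [2.0, 4.0]])  # rows 0 and 2 parallel
        tree = cluster(m)
        a, b, sim = tree.merges[0]
        assert {a, b} == {0, 2}
        assert sim == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 7))
            m = rng.normal(5, 2, size=(n, 5))
            tree = cluster(m)
            expected = brute_force_average_linkage(distance_matrix(m))
            got = [(min(a, b), max(a, b), s) for a, b, s in tree.merges]
            want = [(min(a, b), max(a, b), s) for a, b, s in expected]
            assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in want]
            assert [s for *_, s in got] == pytest.approx([s for *_, s in want], abs=1e-9)

    def test_matches_scipy_average_linkage(self):
        # independent implementation check on tie-free random instances
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(42)
        m = rng.normal(4, 1.5, size=(12, 6))
        d = distance_matrix(m)
        z = linkage(squareform(d, checks=False), method="average")
        tree = cluster(m)
        assert [s for *_, s in tree.merges] == pytest.approx(
            [1.0 - h for h in z[:, 2]], abs=1e-9)
        for (a, b, _), row in zip(tree.merges, z):
            assert {a, b} == {int(row[0]), int(row[1])}

    def test_leaf_order_is_permutation_and_deterministic(self):
        rng = np.random.default_rng(9)
        m = rng.normal(5, 2, size=(8, 4))
        t1, t2 = cluster(m), cluster(m)
        assert sorted(t1.leaf_order) == list(range(8))
        assert t1.leaf_order == t2.leaf_order
        assert t1.merges == t2.merges

    def test_invariant_to_positive_row_rescaling(self):
        rng = np.random.default_rng(10)
        m = rng.normal(5, 2, size=(6, 4))
        scales = rng.uniform(0.5, 10, size=6)[:, None]
        t1, t2 = cluster(m), cluster(m * scales)
        assert [(a, b) for a, b, _ in t1.merges] == [(a, b) for a, b, _ in t2.merges]
        assert [s for *_, s in t1.merges] == pytest.approx([s for *_, s in t2.merges])
        assert t1.leaf_order == t2.leaf_order

    def test_single_and_complete_linkage(self):
        rng = np.random.default_rng(12)
        m = rng.normal(5, 2, size=(7, 4))
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        d = distance_matrix(m)
        for method in ("single", "complete"):
            z = linkage(squareform(d, checks=False), method=method)
            tree = cluster(m, linkage=method)
            assert [s for *_, s in tree.merges] == pytest.approx(
                [1.0 - h for h in z[:, 2]], abs=1e-9)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            cluster(np.array([[1.0, 2.0]]))

    def test_common_signature_splits_by_direction(self, small_noiseless_result):
        result, truth, _ = small_noiseless_result
        tree = result.clustering["genes"]
        genes = [g for g, _ in result.common_full]
        ordered = [genes[i] for i in tree.leaf_order]
        directions = ["up" if g in truth.common_up else "down" for g in ordered]
        # the two planted directions form two contiguous blocks of leaves
        switches = sum(1 for a, b in zip(directions, directions[1:]) if a != b)
        assert switches == 1
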