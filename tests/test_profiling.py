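"""Z-scoring, Ward clustering and partition-recovery metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pathprofiler import (ActivityMatrix, PanelSimSpec, ValidationError,
                          adjusted_rand_index, cut_tree, generate_panel,
                          ward_cluster, zscore_normalize)


def matrix_from(array, normalized=False):
    arr = np.asarray(array, dtype=float)
    vals = pd.DataFrame(arr, index=[f"c{i}" for i in range(arr.shape[0])],
                        columns=[f"a{j}" for j in range(arr.shape[1])])
    m = ActivityMatrix(vals)
    return zscore_normalize(m) if normalized else m


class TestZscore:
    def test_hand_computed_column(self):
        # mu = 2, population sd = sqrt(2/3): [1,2,3] -> [-1.2247, 0, 1.2247]
        z = zscore_normalize(matrix_from([[1, 0], [2, 5], [3, 10]]))
        np.testing.assert_allclose(z.values["a0"], [-1.22474487, 0, 1.22474487],
                                   atol=1e-8)

    def test_constant_column_maps_to_zeros_with_flag(self):
        z = zscore_normalize(matrix_from([[5, 1], [5, 2], [5, 3]]))
        assert (z.values["a0"] == 0).all()
        assert z.normalization_params.loc["a0", "zero_variance"]
        assert not z.normalization_params.loc["a1", "zero_variance"]

    def test_standardized_column_is_fixed_point(self):
        col = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0.0, 1.0])
        z = zscore_normalize(matrix_from(np.column_stack([col, [9, 5, 1]])))
        np.testing.assert_allclose(z.values["a0"], col, atol=1e-12)

    def test_contract_mean_zero_sd_one(self, rng):
        z = zscore_normalize(matrix_from(rng.normal(50, 20, size=(40, 10))))
        arr = z.values.to_numpy()
        assert np.abs(arr.mean(axis=0)).max() < 1e-9
        assert np.abs(arr.std(axis=0) - 1).max() < 1e-9

    def test_single_row_and_double_normalization_rejected(self):
        with pytest.raises(ValidationError):
            zscore_normalize(matrix_from([[1, 2]]))
        z = zscore_normalize(matrix_from([[1, 2], [3, 4]]))
        with pytest.raises(ValidationError):
            zscore_normalize(z)


def brute_force_ward(X):
    """Independent O(n^3) agglomeration: rescan centroid-based Ward distances.

    d^2(A, B) = 2|A||B|/(|A|+|B|) * ||mean_A - mean_B||^2, ties broken by the
    smallest (id_a, id_b) pair; same id scheme as the implementation
    (leaves 0..n-1, merges n, n+1, ...).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for ia, ib in itertools.combinations(sorted(clusters), 2):
            ma = X[clusters[ia]].mean(axis=0)
            mb = X[clusters[ib]].mean(axis=0)
            na, nb = len(clusters[ia]), len(clusters[ib])
            d2 = 2.0 * na * nb / (na + nb) * float(np.sum((ma - mb) ** 2))
            key = (d2, ia, ib)
            if best is None or key < best:
                best = key
        d2, ia, ib = best
        members = clusters.pop(ia) + clusters.pop(ib)
        clusters[next_id] = members
        merges.append((ia, ib, float(np.sqrt(d2)), len(members)))
        next_id += 1
    return merges


class TestWard:
    def test_identical_rows_merge_first_at_height_zero(self):
        X = np.array([[0, 0], [10, 10], [0, 0], [-10, 5]], dtype=float)
        z = matrix_from(X, normalized=True)
        result = ward_cluster(z)
        left, right, height, size = result.merges[0]
        assert (left, right) == (0, 2)
        assert height == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    def test_two_separated_pairs_merge_within_then_across(self):
        X = np.array([[0.0, 0], [1, 1], [100, 100], [101, 101]])
        z = matrix_from(X, normalized=True)
        result = ward_cluster(z)
        merged_pairs = {tuple(m[:2]) for m in result.merges[:2]}
        assert merged_pairs == {(0, 1), (2, 3)}
        assert result.merges[2][2] > max(m[2] for m in result.merges[:2])

    def test_agreement_with_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 7))
            X = rng.normal(size=(n, int(rng.integers(2, 6))))
            z = matrix_from(X, normalized=True)
            mine = ward_cluster(z).merges
            oracle = brute_force_ward(z.values.to_numpy())
            for a, b in zip(mine, oracle):
                assert a[:2] == b[:2] and a[3] == b[3]
                assert a[2] == pytest.approx(b[2], abs=1e-9)

    def test_heights_match_scipy_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage

        z = matrix_from(rng.normal(size=(15, 6)), normalized=True)
        mine = ward_cluster(z).to_linkage()
        ref = linkage(z.values.to_numpy(), method="ward")
        np.testing.assert_allclose(np.sort(mine[:, 2]), np.sort(ref[:, 2]),
                                   atol=1e-8)

    def test_heights_non_decreasing(self, small_panel):
        _, matrix, _, _, _ = small_panel
        result = ward_cluster(zscore_normalize(matrix))
        heights = [m[2] for m in result.merges]
        assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_row_permutation_gives_same_tree_heights(self, rng):
        X = rng.normal(size=(12, 5))
        z1 = matrix_from(X, normalized=True)
        perm = rng.permutation(12)
        z2 = matrix_from(X[perm], normalized=True)
        h1 = [m[2] for m in ward_cluster(z1).merges]
        h2 = [m[2] for m in ward_cluster(z2).merges]
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_requires_normalized_matrix(self, tiny_matrix):
        with pytest.raises(ValidationError):
            ward_cluster(tiny_matrix)


class TestCutTree:
    def test_extreme_cuts(self, small_panel):
        _, matrix, _, _, _ = small_panel
        result = ward_cluster(zscore_normalize(matrix))
        n = result.n_leaves
        singles = cut_tree(result, n)
        assert len(set(singles.values())) == n
        assert set(cut_tree(result, 1).values()) == {0}
        with pytest.raises(ValidationError):
            cut_tree(result, 0)
        with pytest.raises(ValidationError):
            cut_tree(result, n + 1)

    def test_zero_noise_recovery_is_exact(self):
        spec = PanelSimSpec(n_classes=3, n_per_class=6, n_inactive=0,
                            noise_sd=0.0, seed=5)
        matrix, _, _, truth = generate_panel(spec)
        labels = cut_tree(ward_cluster(zscore_normalize(matrix)), 3)
        assert adjusted_rand_index(labels, truth.labels) == pytest.approx(1.0)


def pair_counting_ari(a, b):
    """Brute-force ARI over all compound pairs (Hubert-Arabie closed form)."""
    keys = sorted(a)
    n11 = n00 = n10 = n01 = 0
    for x, y in itertools.combinations(keys, 2):
        sa, sb = a[x] == a[y], b[x] == b[y]
        n11 += sa and sb
        n00 += (not sa) and (not sb)
        n10 += sa and not sb
        n01 += (not sa) and sb
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return num / den if den else 1.0


class TestARI:
    def test_identical_labelings(self):
        labels = {f"c{i}": i % 3 for i in range(12)}
        assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            a = {f"c{i}": int(rng.integers(4)) for i in range(n)}
            b = {f"c{i}": int(rng.integers(4)) for i in range(n)}
            assert adjusted_rand_index(a, b) == pytest.approx(
                pair_counting_ari(a, b), abs=1e-12)

    def test_random_labelings_near_zero(self, rng):
        values = []
        for _ in range(20):
            a = {f"c{i}": int(rng.integers(5)) for i in range(200)}
            b = {f"c{i}": int(rng.integers(5)) for i in range(200)}
            values.append(adjusted_rand_index(a, b))
        assert abs(np.mean(values)) < 0.05

    def test_mismatched_compound_sets_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index({"a": 0}, {"b": 0})
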