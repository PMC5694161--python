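"""Jaccard/Z-score fingerprint and hierarchical clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from molautopsy.fingerprint import (
    cluster_samples,
    collapse_gene_sets,
    compute_fingerprint,
    jaccard_matrix,
    rank_pairs,
    standardize_zscores,
)

from conftest import make_variant


def jaccard_oracle(gene_sets, ids):
    """Direct set arithmetic, independent loop structure."""
    n = len(ids)
    J = np.zeros((n, n))
    for i, j in itertools.product(range(n), range(n)):
        a, b = gene_sets[ids[i]], gene_sets[ids[j]]
        if i == j:
            J[i, j] = 1.0
        elif a | b:
            J[i, j] = len(a & b) / len(a | b)
    return J


class TestCollapseGeneSets:
    def test_collapse_and_category_band(self):
        variants = [
            make_variant(sample="s", pos=1, gene="G1", category=3),
            make_variant(sample="s", pos=2, gene="G1", category=3),
            make_variant(sample="s", pos=3, gene="G2", category=1),
            make_variant(sample="s", pos=4, gene="G3", category=4),
        ]
        assert collapse_gene_sets(variants) == {"s": frozenset({"G1", "G2"})}

    def test_sample_without_band_variants_kept_empty(self):
        variants = [make_variant(sample="s", gene="G", category=5)]
        assert collapse_gene_sets(variants) == {"s": frozenset()}


class TestJaccard:
    def test_small_examples(self):
        sets = {"a": frozenset("AB"), "b": frozenset("BC")}
        J, ids = jaccard_matrix(sets)
        assert J[0, 1] == pytest.approx(1 / 3)
        # the study's strongest pair: 10 shared genes over a union of 96
        assert 10 / 96 == pytest.approx(0.1041667, abs=1e-6)

    def test_identical_and_empty_sets(self):
        sets = {"a": frozenset("AB"), "b": frozenset("AB"), "c": frozenset()}
        J, ids = jaccard_matrix(sets)
        assert J[0, 1] == 1.0
        assert J[0, 2] == 0.0  # empty vs non-empty
        sets2 = {"x": frozenset(), "y": frozenset()}
        J2, _ = jaccard_matrix(sets2)
        assert J2[0, 1] == 0.0  # two empty sets by convention

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            jaccard_matrix({"a": frozenset("A")})

    @given(
        st.dictionaries(
            st.sampled_from([f"s{i}" for i in range(10)]),
            st.frozensets(st.sampled_from(list("ABCDEFG")), max_size=6),
            min_size=2,
            max_size=10,
        )
    )
    def test_matches_set_oracle_and_is_metric_complement(self, sets):
        J, ids = jaccard_matrix(sets)
        assert np.allclose(J, jaccard_oracle(sets, ids))
        assert np.allclose(J, J.T)
        assert (J >= 0).all() and (J <= 1).all()
        # 1 - J obeys the triangle inequality on sampled triples
        for i, j, k in itertools.combinations(range(len(ids)), 3):
            assert 1 - J[i, k] <= (1 - J[i, j]) + (1 - J[j, k]) + 1e-12


class TestStandardize:
    def test_three_sample_hand_computation(self):
        # pairwise J = [1/3, 0, 0]: mean 1/9, sample sd 1/(3*sqrt(3))
        sets = {"s1": frozenset("AB"), "s2": frozenset("BC"), "s3": frozenset("DE")}
        J, ids = jaccard_matrix(sets)
        Z = standardize_zscores(J)
        assert Z[0, 1] == pytest.approx(2 / np.sqrt(3))
        pairs = Z[np.triu_indices(3, k=1)]
        assert pairs.mean() == pytest.approx(0.0, abs=1e-12)
        assert pairs.std(ddof=1) == pytest.approx(1.0)

    def test_degenerate_all_equal_errors(self):
        J = np.full((4, 4), 0.5)
        np.fill_diagonal(J, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            standardize_zscores(J)

    @given(st.integers(0, 2**31 - 1))
    def test_upper_triangle_standardized_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        J = rng.random((n, n))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 1.0)
        Z = standardize_zscores(J)
        pairs = Z[np.triu_indices(n, k=1)]
        assert pairs.mean() == pytest.approx(0.0, abs=1e-10)
        assert pairs.std(ddof=1) == pytest.approx(1.0)
        assert np.allclose(Z, Z.T, equal_nan=True)

    def test_relabeling_permutes_consistently(self):
        rng = np.random.default_rng(0)
        J = rng.random((6, 6))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 1.0)
        perm = rng.permutation(6)
        Z = standardize_zscores(J)
        Zp = standardize_zscores(J[np.ix_(perm, perm)])
        assert np.allclose(Zp, Z[np.ix_(perm, perm)], equal_nan=True)


class TestRankPairs:
    SETS = {"s1": frozenset("AB"), "s2": frozenset("BC"), "s3": frozenset("DE")}

    def _z(self):
        J, ids = jaccard_matrix(self.SETS)
        return standardize_zscores(J), ids

    def test_threshold_selects_expected_pair(self):
        Z, ids = self._z()
        pairs = rank_pairs(Z, self.SETS, ids, z_threshold=1.0)
        assert [p["pair"] for p in pairs] == [("s1", "s2")]
        assert pairs[0]["intersection_genes"] == ["B"]
        assert pairs[0]["n_intersection"] <= pairs[0]["n_union"]

    def test_threshold_above_max_gives_empty(self):
        Z, ids = self._z()
        assert rank_pairs(Z, self.SETS, ids, z_threshold=10.0) == []


def naive_agglomerate(X, method="complete"):
    """Brute-force agglomeration on row vectors; returns merge heights and
    the partition after each merge."""
    clusters = {i: [i] for i in range(len(X))}
    dist = {
        (i, j): float(np.linalg.norm(X[i] - X[j]))
        for i, j in itertools.combinations(range(len(X)), 2)
    }

    def cluster_distance(a, b):
        pairs = [dist[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]]
        if method == "complete":
            return max(pairs)
        if method == "average":
            return sum(pairs) / len(pairs)
        return min(pairs)

    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((a, b) for a, b in itertools.combinations(keys, 2)),
            key=lambda ab: cluster_distance(*ab),
        )
        h = cluster_distance(*best)
        a, b = best
        clusters[a] = clusters[a] + clusters.pop(b)
        partition = frozenset(frozenset(v) for v in clusters.values())
        merges.append((h, partition))
    return merges


def scipy_partitions(link, n):
    """Partition after each scipy merge, for comparison with the oracle."""
    members = {i: frozenset([i]) for i in range(n)}
    alive = set(range(n))
    out = []
    for step, (a, b, h, _) in enumerate(link):
        new = members[int(a)] | members[int(b)]
        members[n + step] = new
        alive -= {int(a), int(b)}
        alive.add(n + step)
        out.append((float(h), frozenset(members[i] for i in alive)))
    return out


class TestClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        X = np.array([[0.0, 1.0], [0.0, 1.0], [5.0, 5.0]])
        link = cluster_samples(X)
        assert link[0, 2] == pytest.approx(0.0)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_merge_count_and_monotone_heights(self):
        rng = np.random.default_rng(1)
        X = rng.random((9, 9))
        link = cluster_samples((X + X.T) / 2)
        assert link.shape[0] == 8
        assert (np.diff(link[:, 2]) >= -1e-12).all()

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_agglomeration_oracle(self, method, seed):
        rng = np.random.default_rng(seed)
        n = 6
        X = rng.random((n, n))
        X = (X + X.T) / 2
        np.fill_diagonal(X, 0.0)
        link = cluster_samples(X, linkage=method)
        got = scipy_partitions(link, n)
        expected = naive_agglomerate(X, method=method)
        for (h1, p1), (h2, p2) in zip(got, expected):
            assert h1 == pytest.approx(h2)
            assert p1 == p2

    def test_four_point_line_geometry(self):
        X = np.array([[0.0], [1.0], [10.0], [11.5]])
        got = scipy_partitions(cluster_samples(X), 4)
        expected = naive_agglomerate(X)
        assert [h for h, _ in got] == pytest.approx([h for h, _ in expected])
        assert got[-2][1] == frozenset({frozenset({0, 1}), frozenset({2, 3})})

    def test_non_finite_entries_fatal(self):
        X = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            cluster_samples(X)

    def test_one_minus_jaccard_distance_mode(self):
        sets = {"a": frozenset("AB"), "b": frozenset("AB"), "c": frozenset("XY")}
        J, _ = jaccard_matrix(sets)
        link = cluster_samples(J, distance="one_minus_jaccard")
        assert link[0, 2] == pytest.approx(0.0)  # identical sets at distance 0


class TestEndToEnd:
    def test_compute_fingerprint_shapes_and_invariants(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(30)]
        variants = []
        pos = 1
        for s in range(8):
            for g in rng.choice(genes, size=10, replace=False):
                variants.append(
                    make_variant(sample=f"s{s}", pos=pos, gene=str(g), category=int(rng.integers(1, 4)))
                )
                pos += 1
        result = compute_fingerprint(variants, z_threshold=1.5)
        n = len(result.sample_ids)
        assert result.jaccard.shape == (n, n)
        assert np.isnan(np.diag(result.zscores)).all()
        assert result.linkage.shape == (n - 1, 4)
        assert sorted(result.leaf_order) == sorted(result.sample_ids)
        for p in result.top_pairs:
            assert p["n_intersection"] <= p["n_union"]
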