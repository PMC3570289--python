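"""Tests for Canberra/WPGMA hierarchical clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import hematrisk as hr
from hematrisk.errors import DegenerateInputError, DimensionError, ParameterError

from conftest import make_matrix


def canberra_reference(x, y):
    """Term-by-term scalar reference computation."""
    total = 0.0
    for xi, yi in zip(x, y):
        den = abs(xi) + abs(yi)
        if den > 0:
            total += abs(xi - yi) / den
    return total


def wpgma_bruteforce(data):
    """Naive WPGMA: recompute the full cluster-distance matrix each step.

    Returns (sorted merge heights, partitions at every k) which are
    invariant to the arbitrary ordering of equal-distance merges.
    """
    n = data.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {
        (i, j): canberra_reference(data[i], data[j])
        for i, j in itertools.combinations(range(n), 2)
    }
    heights = []
    partitions = {n: {frozenset([i]) for i in range(n)}}
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        new_dist = {}
        for (a, b), d in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = d
        for m in clusters:
            d_im = dist[(min(i, m), max(i, m))]
            d_jm = dist[(min(j, m), max(j, m))]
            new_dist[(min(m, next_id), max(m, next_id))] = 0.5 * (d_im + d_jm)
        clusters[next_id] = merged
        dist = new_dist
        partitions[len(clusters)] = set(clusters.values())
        next_id += 1
    return heights, partitions


def partitions_from_dendrogram(dend):
    pos = {leaf: i for i, leaf in enumerate(dend.leaf_ids)}
    out = {}
    for k in range(1, dend.n_leaves + 1):
        assign = hr.cut_tree(dend, k)
        out[k] = {
            frozenset(pos[i] for i in assign.members(lab)) for lab in range(1, k + 1)
        }
    return out


nonneg_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(1, 12),
    elements=st.floats(0, 1e6, allow_nan=False, allow_infinity=False),
)


class TestCanberraDistance:
    def test_identity(self):
        x = np.array([3.0, 0.0, 7.5])
        assert hr.canberra_distance(x, x) == 0.0

    def test_orthogonal_unit_vectors(self):
        assert hr.canberra_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_zero_zero_convention(self):
        assert hr.canberra_distance([0.0, 1.0], [0.0, 1.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            hr.canberra_distance([1.0], [1.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.integers(0, 10_000))
    def test_matches_elementwise_reference(self, dim, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 100, dim), rng.uniform(0, 100, dim)
        assert hr.canberra_distance(x, y) == pytest.approx(canberra_reference(x, y), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_on_positive_orthant(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.uniform(0.01, 100, (3, 6))
        dxy = hr.canberra_distance(x, y)
        assert dxy == pytest.approx(hr.canberra_distance(y, x))
        assert dxy <= hr.canberra_distance(x, z) + hr.canberra_distance(z, y) + 1e-12


class TestAgglomerate:
    def test_two_items_forced_topology(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        dend = hr.agglomerate(m)
        assert dend.n_leaves == 2
        expected = canberra_reference([1.0, 2.0], [3.0, 4.0])
        assert dend.heights[0] == pytest.approx(expected)

    def test_single_item_rejected(self):
        with pytest.raises(DegenerateInputError):
            hr.agglomerate(make_matrix([[1.0, 2.0]]))

    def test_three_collinear_points(self):
        # d(0,1)=1, d(0,10)=1, d(1,10)=9/11: the closest pair is (1, 10)
        dend = hr.agglomerate(make_matrix([[0.0], [1.0], [10.0]]))
        assert dend.heights[0] == pytest.approx(9 / 11)
        first = hr.cut_tree(dend, 2)
        assert first.labels.iloc[1] == first.labels.iloc[2]

    def test_monotone_heights_on_random_data(self):
        rng = np.random.default_rng(1)
        dend = hr.agglomerate(make_matrix(rng.uniform(0, 10, (40, 5))))
        assert (np.diff(dend.heights) >= -1e-9).all()

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_bruteforce_wpgma_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 9))
        data = rng.uniform(0, 10, size=(n, int(rng.integers(2, 6))))
        dend = hr.agglomerate(make_matrix(data))
        oracle_heights, oracle_partitions = wpgma_bruteforce(data)
        assert np.allclose(sorted(dend.heights), sorted(oracle_heights), atol=1e-10)
        got = partitions_from_dendrogram(dend)
        for k, part in oracle_partitions.items():
            assert got[k] == part

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 10, (12, 4))
        ids = [f"P{i}" for i in range(12)]
        a = hr.cut_tree(hr.agglomerate(make_matrix(data, ids=ids)), 3)
        perm = rng.permutation(12)
        b = hr.cut_tree(
            hr.agglomerate(make_matrix(data[perm], ids=[ids[i] for i in perm])), 3
        )
        assert a.partition() == b.partition()

    def test_column_axis_clusters_biomarkers(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 10, (20, 6))
        dend = hr.agglomerate(make_matrix(data), axis="columns")
        assert dend.n_leaves == 6


class TestCutTree:
    def test_root_and_leaf_cuts(self):
        rng = np.random.default_rng(5)
        dend = hr.agglomerate(make_matrix(rng.uniform(0, 10, (9, 3))))
        assert set(hr.cut_tree(dend, 1).labels) == {1}
        leaves = hr.cut_tree(dend, 9)
        assert sorted(leaves.labels) == list(range(1, 10))

    def test_labels_follow_leaf_order(self):
        rng = np.random.default_rng(6)
        dend = hr.agglomerate(make_matrix(rng.uniform(0, 10, (8, 3))))
        assign = hr.cut_tree(dend, 3)
        order = dend.leaf_order()
        seen = []
        for leaf in order:
            lab = assign.labels[leaf]
            if lab not in seen:
                seen.append(lab)
        assert seen == [1, 2, 3]

    def test_out_of_range_k(self):
        dend = hr.agglomerate(make_matrix([[1.0], [2.0], [5.0]]))
        for k in (0, 4):
            with pytest.raises(ParameterError):
                hr.cut_tree(dend, k)


class TestBootstrapStability:
    def test_far_separated_clouds_perfectly_stable(self, planted_two_clouds):
        matrix, _ = planted_two_clouds
        res = hr.bootstrap_stability(matrix, k=2, n_boot=25, seed=0)
        assert np.allclose(res.scores, 1.0)
        assert res.consensus.shape == (30, 30)

    def test_structured_beats_noise(self, planted_two_clouds):
        matrix, _ = planted_two_clouds
        structured = hr.bootstrap_stability(matrix, k=2, n_boot=20, seed=1)
        rng = np.random.default_rng(2)
        noise = make_matrix(rng.uniform(1, 2, (30, 4)))
        unstructured = hr.bootstrap_stability(noise, k=2, n_boot=20, seed=1)
        assert np.nanmean(unstructured.scores) < np.nanmean(structured.scores)

    def test_requires_at_least_one_rep(self, planted_two_clouds):
        with pytest.raises(ParameterError):
            hr.bootstrap_stability(planted_two_clouds[0], k=2, n_boot=0)


class TestExports:
    def test_newick_round_trips_leaf_names(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(7)
        ids = [f"P{i}" for i in range(7)]
        dend = hr.agglomerate(make_matrix(rng.uniform(0, 5, (7, 3)), ids=ids))
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(ids)

    def test_merge_table_shape(self):
        rng = np.random.default_rng(8)
        dend = hr.agglomerate(make_matrix(rng.uniform(0, 5, (6, 3))))
        table = dend.merge_table()
        assert list(table.columns) == ["left", "right", "height", "size"]
        assert len(table) == 5
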