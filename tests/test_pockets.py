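"""Screening, OPTICS clustering, cross-layer merging and ranking."""

import numpy as np
import pytest

from mdpa.pockets import (
    PocketCluster,
    cluster_layer,
    merge_across_layers,
    rank_pockets,
    screen_points,
)
from mdpa.surface import SurfaceLayer


def _layer(d_values, coords=None, n_attach=None):
    d = np.asarray(d_values, dtype=float)
    n = d.size
    lay = SurfaceLayer(
        layer_index=1,
        coords=coords if coords is not None else np.random.default_rng(0).normal(size=(n, 3)),
        probe_radius=1.5, sphere_radius_protein=3.0, sphere_radius_virtual=1.5,
        samples_per_sphere=64, seed=0,
    )
    lay.d_values = d
    lay.n_attachments = (
        np.asarray(n_attach) if n_attach is not None else np.ones(n, dtype=int)
    )
    return lay


def _cluster(coords, layer=1, d=1.0, cid="c"):
    coords = np.atleast_2d(coords)
    return PocketCluster(
        cluster_id=cid, coords=coords,
        layers=np.full(len(coords), layer), d_values=np.full(len(coords), d),
    )


class TestScreenPoints:
    def test_degenerate_equal_values_select_nothing(self):
        lay = _layer([0.3] * 10)
        assert screen_points(lay, z_threshold=1.0).sum() == 0

    def test_single_outlier_selected(self):
        lay = _layer([0.1] * 20 + [5.0])
        sel = screen_points(lay, z_threshold=1.0)
        assert sel.sum() == 1 and sel[-1]

    def test_zero_attachment_points_excluded(self):
        d = [0.0, 0.0, 0.2, 0.3, 0.4, 0.35]
        att = [0, 0, 5, 5, 5, 5]
        sel = screen_points(_layer(d, n_attach=att), z_threshold=1.0)
        assert not sel[0] and not sel[1]
        # statistics computed over the informative points only
        mu, sd = np.mean(d[2:]), np.std(d[2:])
        expected = np.asarray(d) >= mu + sd
        expected[:2] = False
        np.testing.assert_array_equal(sel, expected)

    def test_matches_naive_two_pass_statistics(self):
        rng = np.random.default_rng(4)
        d = rng.gamma(2.0, 0.1, size=200)
        lay = _layer(d)
        sel = screen_points(lay, z_threshold=1.0)
        mu = sum(d) / len(d)
        sd = (sum((x - mu) ** 2 for x in d) / len(d)) ** 0.5
        expected = d >= mu + sd
        np.testing.assert_array_equal(sel, expected)


class TestClusterLayer:
    def test_two_separated_blobs(self):
        """Two dense blobs 30 Å apart: OPTICS must agree with single-linkage
        components at the same radius (independent oracle on separable data)."""
        rng = np.random.default_rng(0)
        a = rng.normal(scale=0.8, size=(20, 3))
        b = rng.normal(scale=0.8, size=(20, 3)) + [30.0, 0, 0]
        pts = np.concatenate([a, b])
        labels = cluster_layer(pts, min_samples=5, max_eps=3.0)
        assert set(labels) == {0, 1}
        assert (labels[:20] == labels[0]).all() and (labels[20:] == labels[20]).all()

        from scipy.cluster.hierarchy import fcluster, linkage

        sl = fcluster(linkage(pts, method="single"), t=3.0, criterion="distance")
        # identical partition up to label names
        assert len(set(sl)) == 2
        assert all((sl == sl[0]) == (labels == labels[0]))

    def test_identical_points_one_cluster(self):
        pts = np.tile([[1.0, 2.0, 3.0]], (8, 1))
        labels = cluster_layer(pts, min_samples=5, max_eps=3.0)
        assert set(labels) == {0}

    def test_sparse_scatter_all_noise(self):
        pts = np.arange(30, dtype=float)[:, None] * [5.0, 0, 0]
        labels = cluster_layer(pts, min_samples=5, max_eps=3.0)
        assert set(labels) == {-1}

    def test_too_few_points_no_clusters(self):
        labels = cluster_layer(np.zeros((3, 3)), min_samples=5, max_eps=3.0)
        assert (labels == -1).all()

    def test_no_cluster_smaller_than_min_samples(self):
        rng = np.random.default_rng(7)
        pts = np.concatenate([
            rng.normal(scale=0.5, size=(12, 3)),
            rng.normal(scale=0.5, size=(2, 3)) + [40.0, 0, 0],  # sub-threshold pair
        ])
        labels = cluster_layer(pts, min_samples=5, max_eps=3.0)
        for lab in set(labels) - {-1}:
            assert (labels == lab).sum() >= 5


class TestMergeAcrossLayers:
    def test_close_clusters_merge(self):
        a = _cluster([[0, 0, 0], [1, 0, 0]], layer=1, cid="a")
        b = _cluster([[3.0, 0, 0], [4.0, 0, 0]], layer=2, cid="b")
        merged = merge_across_layers({1: [a], 2: [b]}, link_distance=3.0)
        assert len(merged) == 1
        parts = merged[0].per_layer_parts()
        assert set(parts) == {1, 2} and parts[1].size == 2 and parts[2].size == 2

    def test_far_clusters_stay_separate(self):
        a = _cluster([[0, 0, 0]], layer=1, cid="a")
        b = _cluster([[10.0, 0, 0]], layer=2, cid="b")
        assert len(merge_across_layers({1: [a], 2: [b]}, link_distance=3.0)) == 2

    def test_matches_bruteforce_transitive_closure(self):
        rng = np.random.default_rng(2)
        clusters = {
            ell: [
                _cluster(rng.uniform(0, 25, size=(rng.integers(2, 6), 3)),
                         layer=ell, cid=f"{ell}.{k}")
                for k in range(3)
            ]
            for ell in (1, 2, 3)
        }
        link = 6.0
        merged = merge_across_layers(clusters, link_distance=link)

        # brute force: pairwise min distances + transitive closure
        flat = [c for ell in sorted(clusters) for c in clusters[ell]]
        k = len(flat)
        adj = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(k):
                dmin = min(
                    np.linalg.norm(p - q)
                    for p in flat[i].coords for q in flat[j].coords
                )
                adj[i, j] = dmin <= link
        reach = adj.copy()
        for _ in range(k):
            reach = reach | (reach @ reach)
        expected_components = {frozenset(np.nonzero(row)[0]) for row in reach}
        assert len(merged) == len(expected_components)
        sizes = sorted(p.n_points for p in merged)
        expected_sizes = sorted(
            sum(flat[i].n_points for i in comp) for comp in expected_components
        )
        assert sizes == expected_sizes

    def test_merged_mean_is_member_weighted(self):
        a = PocketCluster("a", np.zeros((2, 3)), np.ones(2), np.array([1.0, 1.0]))
        b = PocketCluster("b", np.full((3, 3), 0.5), np.full(3, 2), np.array([0.0, 0.0, 0.0]))
        merged = merge_across_layers({1: [a], 2: [b]}, link_distance=3.0)
        assert len(merged) == 1
        assert merged[0].mean_d == pytest.approx((2 * 1.0 + 3 * 0.0) / 5)

    def test_pockets_are_disjoint_point_sets(self, toy, toy_network):
        from mdpa import RunConfig, analyze

        res = analyze(toy.structure, toy.ligand, None, RunConfig(seed=7), network=toy_network)
        seen = set()
        for p in res.pockets:
            for c in p.coords:
                key = tuple(np.round(c, 6))
                assert key not in seen
                seen.add(key)


class TestRankPockets:
    def test_single_pocket_rank_one(self):
        p = _cluster([[0, 0, 0]], d=0.4)
        assert rank_pockets([p])[0].rank == 1

    def test_ordering_by_mean_d(self):
        hi = _cluster([[0, 0, 0]], d=0.5, cid="hi")
        lo = _cluster([[9, 9, 9]], d=0.3, cid="lo")
        ranked = rank_pockets([lo, hi])
        assert [p.cluster_id for p in ranked] == ["hi", "lo"]
        assert [p.rank for p in ranked] == [1, 2]

    def test_tie_broken_by_size(self):
        big = _cluster(np.zeros((10, 3)), d=0.4, cid="big")
        small = _cluster(np.ones((5, 3)), d=0.4, cid="small")
        ranked = rank_pockets([small, big])
        assert ranked[0].cluster_id == "big"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_pockets([])
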