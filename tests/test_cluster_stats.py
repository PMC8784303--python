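import numpy as np
import pytest
from scipy import stats

from oracles import bfs_clusters, exhaustive_sign_flip_p, one_sample_t_flat, paired_t_flat
from specsim import (
    Adjacency,
    ChannelTable,
    SimilarityTensor,
    TMapStack,
    build_adjacency,
    cluster_permutation_test,
    compare_groups,
    extract_cluster_means,
    find_clusters,
    first_level_tmap,
)
from specsim.cluster_stats import NoSignificantClusters
from specsim.rsa_core import GroupSimilarity
from specsim.tfr_data import TimeGrid


def _tensor(z, units=None):
    z = np.asarray(z, dtype=float)
    units = tuple(units) if units is not None else tuple(range(1, z.shape[0] + 1))
    return SimilarityTensor(
        z=z,
        level="within_item",
        subject_id="s",
        unit_ids=units,
        time_grid=TimeGrid(np.arange(z.shape[2]) * 0.1, 0.1),
        channels=ChannelTable(tuple(f"C{i}" for i in range(z.shape[1]))),
    )


class TestFirstLevel:
    @pytest.mark.parametrize(
        "d,expected",
        [([0.0, 1.0, -1.0], 0.0), ([1.0, 2.0, 3.0], 3.4641)],
    )
    def test_hand_computed_paired_t(self, d, expected):
        z_wi = np.array(d)[:, None, None, None] * np.ones((len(d), 1, 2, 2))
        wi = _tensor(z_wi)
        wc = _tensor(np.zeros_like(z_wi))
        t, df = first_level_tmap(wi, wc)
        assert df == len(d) - 1
        np.testing.assert_allclose(t, expected, atol=1e-4)

    def test_matches_flattened_oracle(self, rng):
        z_wi = rng.standard_normal((6, 3, 4, 4))
        z_wc = rng.standard_normal((6, 3, 4, 4))
        t, df = first_level_tmap(_tensor(z_wi), _tensor(z_wc))
        assert df == 5
        np.testing.assert_allclose(t, paired_t_flat(z_wi, z_wc), atol=1e-10)

    def test_units_intersected(self, rng):
        z = rng.standard_normal((4, 1, 2, 2))
        wi = _tensor(z, units=(1, 2, 3, 4))
        wc = _tensor(z[:3] + 1.0, units=(2, 3, 4))
        t, df = first_level_tmap(wi, wc)
        assert df == 2  # categories 2, 3, 4
        np.testing.assert_allclose(t, paired_t_flat(z[1:], z[:3] + 1.0), atol=1e-10)

    def test_too_few_categories_raise(self, rng):
        z = rng.standard_normal((2, 1, 2, 2))
        with pytest.raises(ValueError, match=">= 3"):
            first_level_tmap(_tensor(z), _tensor(z.copy()))


class TestAdjacency:
    def test_collinear_distance_threshold(self):
        ch = ChannelTable(("a", "b", "c"), np.array([[0.0, 0], [1.0, 0], [2.0, 0]]))
        adj = build_adjacency(ch, "distance_threshold", 1.1)
        assert adj.pairs == ((0, 1), (1, 2))

    def test_zero_threshold_gives_empty_graph(self):
        ch = ChannelTable(("a", "b"), np.array([[0.0, 0], [1.0, 0]]))
        assert build_adjacency(ch, "distance_threshold", 0).pairs == ()

    def test_explicit_list_file_round_trip(self, tmp_path):
        ch = ChannelTable(("a", "b", "c"), None)
        adj = build_adjacency(ch, "explicit_list", [("a", "b"), ("c", "b")])
        f = tmp_path / "neighbors.txt"
        f.write_text("\n".join(f"{ch.labels[i]} {ch.labels[j]}" for i, j in adj.pairs))
        assert build_adjacency(ch, "explicit_list", f).pairs == adj.pairs

    def test_missing_positions_raise(self):
        with pytest.raises(ValueError, match="positions"):
            build_adjacency(ChannelTable(("a", "b"), None), "distance_threshold", 1)

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="irreflexive"):
            Adjacency(("a", "b"), ((0, 0),))


LINE3 = Adjacency(("a", "b", "c"), ((0, 1), (1, 2)))


class TestFindClusters:
    def test_subthreshold_map_has_no_clusters(self, rng):
        tmap = 0.1 * rng.standard_normal((3, 4, 4))
        _, _, clusters = find_clusters(tmap, 2.0, LINE3)
        assert clusters == []

    def test_cross_pattern_single_cluster_mass(self):
        tmap = np.zeros((1, 3, 3))
        cross = [(0, 1), (1, 0), (1, 1), (1, 2), (2, 1)]
        for i, j in cross:
            tmap[0, i, j] = 3.0 + i + j
        lp, _, clusters = find_clusters(tmap, 2.0, Adjacency(("a",), ()))
        assert len(clusters) == 1
        assert clusters[0]["mass"] == pytest.approx(sum(3.0 + i + j for i, j in cross))
        assert clusters[0]["n_samples"] == 5

    def test_diagonal_moves_do_not_connect(self):
        tmap = np.zeros((1, 4, 4))
        tmap[0, 0, 0] = tmap[0, 1, 1] = 5.0
        _, _, clusters = find_clusters(tmap, 2.0, Adjacency(("a",), ()))
        assert len(clusters) == 2

    def test_non_adjacent_channels_stay_separate(self):
        tmap = np.zeros((3, 3, 3))
        tmap[0, 1, 1] = tmap[2, 1, 1] = 5.0
        _, _, clusters = find_clusters(tmap, 2.0, LINE3)
        assert len(clusters) == 2
        # with the bridging middle channel active they merge
        tmap[1, 1, 1] = 5.0
        _, _, merged = find_clusters(tmap, 2.0, LINE3)
        assert len(merged) == 1
        assert merged[0]["channels"] == (0, 1, 2)

    def test_matches_bfs_oracle_on_random_maps(self, rng):
        adj = Adjacency(("a", "b", "c", "d"), ((0, 1), (1, 2), (2, 3), (0, 3)))
        for _ in range(25):
            tmap = rng.standard_normal((4, 6, 6))
            lp, ln, clusters = find_clusters(tmap, 1.0, adj)
            for sign, labels in ((+1, lp), (-1, ln)):
                mask = tmap > 1.0 if sign > 0 else tmap < -1.0
                expected = bfs_clusters(mask, tmap, adj.pairs)
                got = set()
                for cid in np.unique(labels[labels > 0]):
                    cells = frozenset(zip(*(x.tolist() for x in np.nonzero(labels == cid))))
                    mass = round(float(tmap[labels == cid].sum()), 9)
                    got.add((cells, mass))
                assert got == expected

    def test_matches_mne_single_channel(self, rng):
        from mne.stats import permutation_cluster_1samp_test

        X = rng.standard_normal((8, 12, 12)) + 0.35
        thr = stats.t.ppf(1 - 0.025, 7)
        t_obs, mne_clusters, _, _ = permutation_cluster_1samp_test(
            X, threshold=thr, tail=0, n_permutations=2, adjacency=None,
            out_type="mask", seed=0, verbose=False,
        )
        masses_mne = sorted(float(t_obs[m].sum()) for m in mne_clusters)
        _, _, clusters = find_clusters(t_obs[np.newaxis], thr, Adjacency(("a",), ()))
        assert sorted(c["mass"] for c in clusters) == pytest.approx(masses_mne)


class TestPermutationTest:
    def test_floor_p_at_500_draws(self, rng):
        # strong homogeneous effect: observed mass exceeds every null draw
        maps = 1.0 + 0.05 * rng.standard_normal((20, 1, 5, 5))
        res = cluster_permutation_test(
            TMapStack(maps, df=9), Adjacency(("a",), ()), n_perm=500, seed=0
        )
        top = max(res.clusters, key=lambda c: c["mass"])
        assert top["p_value"] == pytest.approx(0.002)
        assert res.n_permutations == 500

    def test_matches_exhaustive_enumeration(self, rng):
        maps = rng.standard_normal((8, 2, 4, 4)) + 0.6
        adj = Adjacency(("a", "b"), ((0, 1),))
        df = 7
        thr = stats.t.ppf(1 - 0.025, df)
        exact = exhaustive_sign_flip_p(maps, thr, adj.pairs)
        res = cluster_permutation_test(
            TMapStack(maps, df=5), adj, n_perm=256, seed=3
        )
        assert res.sample_threshold == pytest.approx(thr)
        tol = 2.0 / np.sqrt(256)
        for c in res.clusters:
            exact_p = (
                exact["p_pos"][round(c["mass"], 9)]
                if c["sign"] > 0
                else exact["p_neg"][round(c["mass"], 9)]
            )
            assert c["p_value"] == pytest.approx(exact_p, abs=tol)

    def test_global_sign_flip_swaps_cluster_lists(self, rng):
        maps = rng.standard_normal((10, 2, 5, 5)) + 0.4
        adj = Adjacency(("a", "b"), ((0, 1),))
        res_pos = cluster_permutation_test(TMapStack(maps, df=9), adj, n_perm=64, seed=5)
        res_neg = cluster_permutation_test(TMapStack(-maps, df=9), adj, n_perm=64, seed=5)
        pos = sorted((c["mass"], c["p_value"]) for c in res_pos.clusters if c["sign"] > 0)
        neg = sorted(
            (-c["mass"], c["p_value"]) for c in res_neg.clusters if c["sign"] < 0
        )
        assert pos == pytest.approx(neg)
        np.testing.assert_allclose(res_pos.ref_pos, -res_neg.ref_neg)

    def test_subject_relabeling_leaves_pvalues_stable(self, rng):
        maps = rng.standard_normal((10, 1, 5, 5)) + 0.5
        adj = Adjacency(("a",), ())
        res_a = cluster_permutation_test(TMapStack(maps, df=9), adj, n_perm=400, seed=7)
        perm = rng.permutation(10)
        res_b = cluster_permutation_test(
            TMapStack(maps[perm], df=9), adj, n_perm=400, seed=8
        )
        pa = sorted(c["p_value"] for c in res_a.clusters)
        pb = sorted(c["p_value"] for c in res_b.clusters)
        assert len(pa) == len(pb)  # observed map identical up to fp order
        np.testing.assert_allclose(pa, pb, atol=3.0 / np.sqrt(400))

    def test_low_n_perm_warns(self, rng):
        maps = rng.standard_normal((4, 1, 3, 3))
        with pytest.warns(UserWarning, match="cannot reject"):
            cluster_permutation_test(
                TMapStack(maps, df=3), Adjacency(("a",), ()), n_perm=10, seed=0
            )

    def test_zero_group_mode_agrees_on_strong_effect(self, rng):
        maps = 1.0 + 0.05 * rng.standard_normal((16, 1, 4, 4))
        adj = Adjacency(("a",), ())
        res = cluster_permutation_test(
            TMapStack(maps, df=9), adj, n_perm=200, seed=1, mode="zero_group"
        )
        top = max(res.clusters, key=lambda c: c["mass"])
        assert top["p_value"] < 0.025


def _group(stack, group="children"):
    return GroupSimilarity(
        stack=np.asarray(stack, dtype=float),
        group=group,
        level="within_item",
        subject_ids=tuple(f"s{i}" for i in range(len(stack))),
    )


def _result_with_mask(mask, p=0.002):
    mask = np.asarray(mask)
    labels = mask.astype(np.int64)
    return __import__("specsim").ClusterResult(
        labels_pos=labels,
        labels_neg=np.zeros_like(labels),
        clusters=[
            {
                "id": 1,
                "sign": 1,
                "mass": 10.0,
                "n_samples": int(mask.sum()),
                "channels": (0,),
                "p_value": p,
            }
        ],
        ref_pos=np.zeros(500),
        ref_neg=np.zeros(500),
        n_permutations=500,
        sample_threshold=2.0,
        sample_alpha=0.05,
        cluster_alpha=0.025,
    )


class TestExtractClusterMeans:
    def test_single_sample_mask(self, rng):
        wi = rng.standard_normal((3, 2, 4, 4))
        wc = rng.standard_normal((3, 2, 4, 4))
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[1, 2, 3] = True
        summ = extract_cluster_means(_group(wi), _group(wc), _result_with_mask(mask))
        np.testing.assert_allclose(summ.mean_within_item_z, wi[:, 1, 2, 3])
        np.testing.assert_allclose(summ.mean_within_category_z, wc[:, 1, 2, 3])
        assert summ.n_mask_samples == 1

    def test_identical_stacks_give_zero_specificity(self, rng):
        wi = rng.standard_normal((4, 2, 3, 3))
        mask = np.ones((2, 3, 3), dtype=bool)
        summ = extract_cluster_means(
            _group(wi), _group(wi.copy()), _result_with_mask(mask)
        )
        np.testing.assert_allclose(summ.specificity, 0.0)

    def test_delta_identity_exact(self, rng):
        wi = rng.standard_normal((5, 2, 3, 3))
        wc = rng.standard_normal((5, 2, 3, 3))
        mask = rng.random((2, 3, 3)) > 0.5
        summ = extract_cluster_means(_group(wi), _group(wc), _result_with_mask(mask))
        np.testing.assert_array_equal(
            summ.specificity, summ.mean_within_item_z - summ.mean_within_category_z
        )

    def test_no_significant_cluster_raises(self, rng):
        wi = rng.standard_normal((3, 2, 3, 3))
        res = _result_with_mask(np.zeros((2, 3, 3), dtype=bool), p=0.5)
        with pytest.raises(NoSignificantClusters):
            extract_cluster_means(_group(wi), _group(wi), res)


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_pooled_t(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(
            2 * stats.t.sf(3.674, 4), abs=1e-3
        )

    def test_degenerate_equal_constant_groups(self):
        t, p = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [1.0, 2.0])
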