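import numpy as np
import pandas as pd
import pytest

import topicspot as ts
from topicspot.deconvolution import SpotComposition, SpotTopicDistribution

from conftest import make_coords


def comp_of(values, types=None, spots=None):
    values = np.asarray(values, dtype=float)
    types = types or [f"t{i}" for i in range(values.shape[0])]
    spots = spots or [f"s{j}" for j in range(values.shape[1])]
    return SpotComposition(values, types, spots)


class TestNeighborhoodComposition:
    def test_uniform_field_is_unchanged(self):
        comp = comp_of(np.tile([[0.7], [0.3]], (1, 9)))
        xy = np.array([(i, j) for i in range(3) for j in range(3)], float)
        coords = make_coords(comp.spot_ids, xy)
        out = ts.neighborhood_composition(comp, coords)
        np.testing.assert_allclose(out, comp.proportions)

    def test_single_spot_falls_back_to_itself(self):
        comp = comp_of([[0.6], [0.4]])
        coords = make_coords(["s0"], np.array([[0.0, 0.0]]))
        out = ts.neighborhood_composition(comp, coords)
        np.testing.assert_allclose(out, comp.proportions)

    def test_collinear_middle_is_mean_of_flanks(self):
        comp = comp_of([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]])
        coords = make_coords(comp.spot_ids,
                             np.array([[0, 0], [1, 0], [2, 0]], float))
        out = ts.neighborhood_composition(comp, coords, k_neighbors=2)
        np.testing.assert_allclose(out[:, 1], [0.5, 0.5])

    def test_radius_rule(self):
        comp = comp_of([[1.0, 0.0, 0.4], [0.0, 1.0, 0.6]])
        coords = make_coords(comp.spot_ids,
                             np.array([[0, 0], [1, 0], [50, 0]], float))
        out = ts.neighborhood_composition(comp, coords, radius=2.0)
        np.testing.assert_allclose(out[:, 0], [0.0, 1.0])  # only neighbor s1
        np.testing.assert_allclose(out[:, 2], [0.4, 0.6])  # isolated


class TestClusterDomains:
    @pytest.fixture()
    def blobs(self):
        rng = np.random.default_rng(0)
        n = 15
        xy = np.vstack([rng.uniform(0, 3, (n, 2)), rng.uniform(20, 23, (n, 2))])
        prop = np.zeros((2, 2 * n))
        prop[0, :n], prop[1, :n] = 0.9, 0.1
        prop[0, n:], prop[1, n:] = 0.1, 0.9
        comp = comp_of(prop)
        return comp, make_coords(comp.spot_ids, xy), n

    def test_separated_blobs_form_clusters(self, blobs):
        comp, coords, n = blobs
        cl = ts.cluster_domains(comp, coords, k_clusters=2, seed=0)
        assert len(set(cl.iloc[:n])) == 1
        assert len(set(cl.iloc[n:])) == 1
        assert cl.iloc[0] != cl.iloc[-1]

    def test_weight_one_ignores_coordinates(self, blobs):
        comp, coords, n = blobs
        rng = np.random.default_rng(1)
        shuffled_xy = coords.xy(comp.spot_ids)[rng.permutation(2 * n)]
        other = make_coords(comp.spot_ids, shuffled_xy)
        a = ts.cluster_domains(comp, coords, k_clusters=2, weight=1.0, seed=0)
        b = ts.cluster_domains(comp, other, k_clusters=2, weight=1.0, seed=0)
        # same partition regardless of geometry
        assert (a == a.iloc[0]).equals(b == b.iloc[0])

    def test_spot_order_invariance_up_to_relabeling(self, blobs):
        comp, coords, n = blobs
        rng = np.random.default_rng(2)
        perm = rng.permutation(2 * n)
        comp2 = comp_of(comp.proportions[:, perm],
                        spots=[comp.spot_ids[i] for i in perm])
        a = ts.cluster_domains(comp, coords, k_clusters=2, seed=0)
        b = ts.cluster_domains(comp2, coords, k_clusters=2, seed=0)
        b = b.reindex(a.index)
        same_a = a.to_numpy()[:, None] == a.to_numpy()[None, :]
        same_b = b.to_numpy()[:, None] == b.to_numpy()[None, :]
        assert (same_a == same_b).all()

    def test_too_many_clusters_is_error(self, blobs):
        comp, coords, _ = blobs
        with pytest.raises(ValueError):
            ts.cluster_domains(comp, coords, k_clusters=100)


class TestDefineRegions:
    @pytest.fixture()
    def line(self):
        # spots on a line at x = 0..12; core cluster at x <= 2
        xy = np.array([[x, 0.0] for x in range(13)])
        ids = [f"s{x}" for x in range(13)]
        clusters = pd.Series([0] * 3 + [1] * 10, index=ids)
        return clusters, make_coords(ids, xy)

    def test_distance_thresholds(self, line):
        clusters, coords = line
        out = ts.define_regions(clusters, coords, core_cluster=0,
                                threshold=4.0, edge_radius=2.0)
        assert (out.loc[["s0", "s1", "s2"], "region"] == "core").all()
        assert (out.loc[["s0", "s1", "s2"], "distance_to_core"] == 0).all()
        assert out.loc["s3", "region"] == "edge"      # distance 1
        assert out.loc["s4", "region"] == "edge"      # distance 2 (= radius)
        assert out.loc["s5", "region"] == "border"    # distance 3
        assert out.loc["s6", "region"] == "border"    # distance 4 == threshold
        assert out.loc["s7", "region"] == "stroma"    # distance 5
        assert out.loc["s12", "region"] == "stroma"   # distance 10

    def test_regions_partition_non_core(self, line):
        clusters, coords = line
        out = ts.define_regions(clusters, coords, core_cluster=0)
        non_core = out[out.region != "core"]
        assert set(non_core.region) <= {"edge", "border", "stroma"}
        assert non_core.region.notna().all()

    def test_empty_core_is_error(self, line):
        clusters, coords = line
        with pytest.raises(ValueError, match="empty"):
            ts.define_regions(clusters, coords, core_cluster=9)


class TestQuotas:
    def test_hand_case(self):
        np.testing.assert_array_equal(
            ts.largest_remainder_quota(np.array([0.55, 0.45]), 10), [6, 4]
        )

    def test_brute_force_deviation_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            q = ts.largest_remainder_quota(p, 10)
            assert q.sum() == 10
            assert (np.abs(q - p * 10) < 1.0).all()


class TestMapCellsToSpots:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(6)
        k, m = 4, 20
        z = rng.dirichlet(np.ones(k), m).T
        cell_ids = [f"c{i:02d}" for i in range(m)]
        types = {c: ("A" if i < 10 else "B") for i, c in enumerate(cell_ids)}
        return z, cell_ids, types

    def test_identical_profile_cell_is_selected(self, toy):
        z, cell_ids, types = toy
        y = SpotTopicDistribution(z[:, [3]].copy(), ["spot0"])
        comp = comp_of([[1.0], [0.0]], types=["A", "B"], spots=["spot0"])
        out = ts.map_cells_to_spots(z, cell_ids, types, y, comp, n_cells=1)
        assert out.selected["spot0"] == ["c03"]

    def test_matches_exhaustive_cosine_ranking(self, toy):
        z, cell_ids, types = toy
        rng = np.random.default_rng(7)
        yv = rng.dirichlet(np.ones(4))
        y = SpotTopicDistribution(yv[:, None], ["spot0"])
        comp = comp_of([[0.55], [0.45]], types=["A", "B"], spots=["spot0"])
        out = ts.map_cells_to_spots(z, cell_ids, types, y, comp, n_cells=10)
        # brute-force oracle: cosine similarity, top 6 A cells and 4 B cells
        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        expect = []
        for t, q in (("A", 6), ("B", 4)):
            pool = [i for i, c in enumerate(cell_ids) if types[c] == t]
            ranked = sorted(pool, key=lambda i: (-cos(z[:, i], yv), cell_ids[i]))
            expect += [cell_ids[i] for i in ranked[:q]]
        assert sorted(out.selected["spot0"]) == sorted(expect)

    def test_quota_beyond_pool_recycles(self, toy):
        z, cell_ids, types = toy
        few = {c: t for c, t in types.items() if t == "B" or c in ("c00",)}
        keep = [i for i, c in enumerate(cell_ids) if c in few]
        z2 = z[:, keep]
        ids2 = [cell_ids[i] for i in keep]
        y = SpotTopicDistribution(z2[:, [0]].copy(), ["spot0"])
        comp = comp_of([[0.5], [0.5]], types=["A", "B"], spots=["spot0"])
        out = ts.map_cells_to_spots(z2, ids2, few, y, comp, n_cells=10)
        # quota of 5 for type A with a single cell: recycled
        assert out.selected["spot0"].count("c00") == 5

    def test_cosine_scale_invariance(self, toy):
        z, cell_ids, types = toy
        y = SpotTopicDistribution(z[:, [5]] * 7.0, ["spot0"])
        comp = comp_of([[1.0], [0.0]], types=["A", "B"], spots=["spot0"])
        out = ts.map_cells_to_spots(z, cell_ids, types, y, comp, n_cells=1)
        assert out.selected["spot0"] == ["c05"]

    def test_pooled_expression_sums_selected_cells(self, toy, block3):
        sc, labels = block3
        model_z = np.eye(3)[:, [0, 1, 2] * 40]  # fake topic columns
        cell_ids = sc.column_ids
        types = labels.assignments
        y = SpotTopicDistribution(np.array([[1.0], [0.0], [0.0]]), ["spot0"])
        ctypes = labels.cell_types
        comp = comp_of(np.array([[1.0], [0.0], [0.0]]), types=ctypes,
                       spots=["spot0"])
        out = ts.map_cells_to_spots(model_z, cell_ids, types, y, comp,
                                    sc=sc, n_cells=2)
        picked = out.selected["spot0"]
        t = types[picked[0]]
        expected = sum(sc.values[:, sc.column_ids.index(c)] for c in picked)
        np.testing.assert_array_equal(
            out.pooled[t]["spot0"].to_numpy(), expected
        )
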