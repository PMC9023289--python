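import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import topicspot as ts
from topicspot.simulation import (
    CompartmentRule,
    _largest_remainder,
    downsample_counts,
)


class TestDownsampleCounts:
    def test_target_above_total_is_unchanged(self):
        rng = np.random.default_rng(0)
        v = np.array([5, 0, 3])
        np.testing.assert_array_equal(downsample_counts(v, 100, rng), v)

    def test_negative_target_is_error(self):
        with pytest.raises(ValueError):
            downsample_counts(np.array([1]), -1, np.random.default_rng(0))

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 500), min_size=2, max_size=8),
           st.integers(0, 400))
    def test_sum_exact_and_elementwise_bounded(self, counts, target):
        v = np.array(counts)
        out = downsample_counts(v, target, np.random.default_rng(1))
        assert out.sum() == min(target, v.sum())
        assert (out <= v).all()
        assert (out >= 0).all()

    def test_preserves_mass_fractions(self):
        # one gene holds half the input mass; at target 10,000 its share
        # stays within a generous binomial 99% interval around 0.5
        v = np.array([20_000, 10_000, 10_000])
        out = downsample_counts(v, 10_000, np.random.default_rng(2))
        share = out[0] / out.sum()
        half_width = 2.576 * np.sqrt(0.25 / 10_000)
        assert abs(share - 0.5) < half_width * 1.5


class TestRandomSpots:
    @pytest.fixture(scope="module")
    def dataset(self, block3):
        sc, labels = block3
        return sc, labels, ts.simulate_random_spots(
            sc, labels, n_spots=50, seed=7
        )

    def test_truth_counts_cell_types(self, dataset):
        sc, labels, ds = dataset
        for j, cells in enumerate(ds.provenance):
            types = [labels.assignments[c] for c in cells]
            expected = np.array(
                [types.count(t) / len(types) for t in ds.cell_types]
            )
            np.testing.assert_allclose(ds.truth[:, j], expected)

    def test_cells_per_spot_within_bounds(self, dataset):
        _, _, ds = dataset
        sizes = [len(p) for p in ds.provenance]
        assert min(sizes) >= 2 and max(sizes) <= 10

    def test_spot_column_is_sum_of_provenance(self, dataset):
        sc, _, ds = dataset
        idx = {c: i for i, c in enumerate(sc.column_ids)}
        for j, cells in enumerate(ds.provenance):
            total = sum(sc.values[:, idx[c]].sum() for c in cells)
            if total <= 25_000:  # uncapped spots: exact integer identity
                expected = sum(sc.values[:, idx[c]] for c in cells)
                np.testing.assert_array_equal(ds.st_matrix.values[:, j],
                                              expected)

    def test_cap_triggers_downsampling_to_target(self, block3):
        sc, labels = block3
        # stack enough cells that the aggregate exceeds the UMI cap
        ds = ts.simulate_random_spots(
            sc, labels, n_spots=5, cells_min=25, cells_max=30, seed=8
        )
        totals = ds.st_matrix.column_totals()
        assert (totals == 20_000).all()

    def test_below_cap_untouched(self, block3):
        sc, labels = block3
        ds = ts.simulate_random_spots(sc, labels, n_spots=5, cells_min=2,
                                      cells_max=3, seed=9)
        idx = {c: i for i, c in enumerate(sc.column_ids)}
        for j, cells in enumerate(ds.provenance):
            assert ds.st_matrix.values[:, j].sum() == sum(
                sc.values[:, idx[c]].sum() for c in cells
            )

    def test_cells_max_above_population_is_error(self, block3):
        sc, labels = block3
        with pytest.raises(ValueError):
            ts.simulate_random_spots(sc, labels, n_spots=1,
                                     cells_max=sc.n_columns + 1)


class TestDepthSeries:
    @pytest.fixture(scope="module")
    def series(self, block3):
        sc, labels = block3
        return ts.simulate_depth_series(sc, labels, n_spots=20,
                                        depths=[10_000, 5_000, 2_500], seed=3)

    def test_column_sums_are_min_of_depth_and_base(self, series, block3):
        sc, labels = block3
        base = ts.simulate_random_spots(sc, labels, n_spots=20, cells_min=10,
                                        cells_max=10, umi_cap=None, seed=3)
        base_totals = base.st_matrix.column_totals()
        for depth, ds in series.items():
            np.testing.assert_array_equal(
                ds.st_matrix.column_totals(),
                np.minimum(depth, base_totals),
            )

    def test_truth_shared_across_levels(self, series):
        levels = list(series.values())
        for ds in levels[1:]:
            np.testing.assert_array_equal(ds.truth, levels[0].truth)
            assert ds.provenance == levels[0].provenance

    def test_nested_levels_are_contained(self, series):
        depths = sorted(series, reverse=True)
        for hi, lo in zip(depths, depths[1:]):
            assert (series[lo].st_matrix.values
                    <= series[hi].st_matrix.values).all()


class TestTME:
    @pytest.fixture(scope="module")
    def tme(self):
        sc, labels = ts.make_block_fixture(
            n_types=11, genes_per_type=15, cells_per_type=60, depth=2000,
            seed=3,
        )
        return labels, ts.simulate_tme(sc, labels, seed=4)

    def test_region_spot_counts(self, tme):
        _, ds = tme
        regions = np.array(ds.spot_region)
        counts = {r: int((regions == r).sum()) for r in set(regions)}
        assert counts == {"TC": 250, "IM": 250, "TS": 250, "TLS": 250}

    def test_excluded_types_are_exactly_zero(self, tme):
        _, ds = tme
        tf = ds.truth_frame()
        regions = np.array(ds.spot_region)
        # malignant cells never appear in the lymphoid structure,
        # B/plasma/endothelial etc. never in the tumor core
        assert (tf.loc["Malignant", regions == "TLS"] == 0).all()
        for absent in ["B", "Plasma", "Tprolif", "Endothelial",
                       "Fibroblasts", "Myofibroblasts"]:
            assert (tf.loc[absent, regions == "TC"] == 0).all()
        for absent in ["Malignant", "Mono/Macro", "Mast", "Tprolif",
                       "Myofibroblasts"]:
            assert (tf.loc[absent, regions == "TLS"] == 0).all()

    def test_colocalized_pairs_hit_target_correlation(self, tme):
        _, ds = tme
        tf = ds.truth_frame()
        regions = np.array(ds.spot_region)
        for region, a, b in [("TC", "Malignant", "CD8T"),
                             ("IM", "Malignant", "Fibroblasts"),
                             ("TLS", "CD4T", "B")]:
            sub = tf.loc[:, regions == region]
            r = np.corrcoef(sub.loc[a], sub.loc[b])[0, 1]
            assert abs(r - 0.7) <= 0.1, (region, a, b, r)

    def test_truth_columns_sum_to_one(self, tme):
        _, ds = tme
        np.testing.assert_allclose(ds.truth.sum(axis=0), 1.0, atol=1e-9)

    def test_infeasible_rule_is_error(self):
        with pytest.raises(ValueError, match="fixed fractions"):
            CompartmentRule(region="X", n_spots=10,
                            fixed={"A": 0.6, "B": 0.5}, free=["C"])

    def test_unknown_type_in_rules_is_error(self, block3):
        sc, labels = block3
        with pytest.raises(ValueError, match="absent from labels"):
            ts.simulate_tme(sc, labels, seed=0)


class TestLargestRemainder:
    def test_hand_case(self):
        np.testing.assert_array_equal(
            _largest_remainder(np.array([0.55, 0.45]), 10), [6, 4]
        )

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0.01, 1, allow_nan=False), min_size=2,
                    max_size=6), st.integers(1, 20))
    def test_sums_and_stays_within_one_unit(self, fracs, total):
        f = np.array(fracs)
        counts = _largest_remainder(f, total)
        assert counts.sum() == total
        quota = f / f.sum() * total
        assert (np.abs(counts - quota) < 1.0).all()


class TestBlockFixture:
    def test_construction_counts(self):
        sc, labels = ts.make_block_fixture(n_types=5, genes_per_type=20,
                                           cells_per_type=10, seed=0)
        markers = [g for g in sc.gene_ids if g.startswith("MK")]
        assert len(markers) == 100
        assert sc.n_columns == 50
        assert len(labels.cell_types) == 5

    def test_same_seed_identical(self):
        a, _ = ts.make_block_fixture(n_types=2, cells_per_type=5, seed=5)
        b, _ = ts.make_block_fixture(n_types=2, cells_per_type=5, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_dimensions_error(self):
        with pytest.raises(ValueError):
            ts.make_block_fixture(n_types=0)
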