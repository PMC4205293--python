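import numpy as np
import pytest
from hypothesis import given, strategies as st

from refugia.enm import (
    RANGE_EXPANSION,
    RANGE_RETRACTION,
    RANGE_STABILITY,
    classification_association,
    classify_dynamics,
    classify_stack_dynamics,
    compute_tss,
    consensus_map,
    map_centroid,
    range_size,
    refugium_map,
    variance_partition,
)
from refugia.grids import Grid, SuitabilityStack
from refugia.synthetic import SyntheticMapSpec, gen_suitability_stack


def _stack(values, tss=None, periods=None):
    values = np.asarray(values, dtype=float)
    n_a, n_g, n_t = values.shape[:3]
    if tss is None:
        tss = np.ones((n_a, n_g))
    return SuitabilityStack(
        values=values,
        algorithms=[f"a{i}" for i in range(n_a)],
        aogcms=[f"g{i}" for i in range(n_g)],
        periods=periods or [f"t{i}" for i in range(n_t)],
        tss=np.asarray(tss, dtype=float),
    )


class TestTss:
    def test_perfect_and_random_prediction(self):
        assert compute_tss(10, 0, 10, 0) == pytest.approx(1.0)
        assert compute_tss(5, 5, 5, 5) == pytest.approx(0.0)

    def test_worked_confusion_table(self):
        assert compute_tss(40, 10, 30, 20) == pytest.approx(0.4)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_tss(0, 0, 5, 5)


class TestConsensus:
    def test_equal_weights_arithmetic_mean(self):
        vals = np.zeros((2, 1, 1, 1, 1))
        vals[0] = 0.2
        vals[1] = 0.8
        st_ = _stack(vals)
        assert consensus_map(st_, 0).data[0, 0] == pytest.approx(0.5)

    def test_weighted_mean(self):
        vals = np.zeros((2, 1, 1, 1, 1))
        vals[0] = 0.2
        vals[1] = 0.8
        st_ = _stack(vals, tss=[[1.0], [3.0]])
        assert consensus_map(st_, 0).data[0, 0] == pytest.approx(0.65)

    def test_single_nonzero_weight_returns_that_layer(self):
        vals = np.random.default_rng(0).uniform(size=(3, 1, 1, 4, 4))
        st_ = _stack(vals, tss=[[0.0], [0.7], [0.0]])
        np.testing.assert_allclose(consensus_map(st_, 0).data, vals[1, 0, 0])

    def test_negative_weights_floored(self):
        vals = np.zeros((2, 1, 1, 1, 1))
        vals[0] = 0.2
        vals[1] = 0.8
        st_ = _stack(vals, tss=[[-0.5], [0.5]])
        assert consensus_map(st_, 0).data[0, 0] == pytest.approx(0.8)

    def test_all_zero_weights_rejected(self):
        st_ = _stack(np.full((2, 1, 1, 1, 1), 0.5), tss=[[0.0], [0.0]])
        with pytest.raises(ValueError):
            consensus_map(st_, 0)


class TestRangeSize:
    def test_threshold_is_inclusive(self):
        grid = Grid(np.array([[0.31, 0.29, 0.30]]))
        assert range_size(grid, 0.3) == 2

    def test_empty_and_full(self):
        assert range_size(Grid(np.zeros((3, 3))), 0.3) == 0
        assert range_size(Grid(np.random.default_rng(1).uniform(size=(3, 3))), 0.0) == 9


class TestClassification:
    @pytest.mark.parametrize(
        "old, recent, label",
        [
            (1000, 1000, RANGE_STABILITY),
            (1000, 1250, RANGE_EXPANSION),  # diff -250 < -199
            (1000, 1199, RANGE_STABILITY),  # diff -199 boundary inclusive
            (1199, 1000, RANGE_STABILITY),  # diff +199 boundary inclusive
            (1300, 1000, RANGE_RETRACTION),  # diff +300 > 199
        ],
    )
    def test_cutoff_rule(self, old, recent, label):
        assert classify_dynamics(old, recent) == label

    @given(st.integers(0, 5_000), st.integers(0, 5_000), st.integers(0, 2_000))
    def test_shift_invariance(self, old, recent, shift):
        # adding the same suitable area to both periods keeps the label
        assert classify_dynamics(old, recent) == classify_dynamics(old + shift, recent + shift)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamics(-1, 10)


class TestRefugium:
    def test_cellwise_rule(self):
        maps = [Grid(np.array([[0.4, 0.4, 1.0]])), Grid(np.array([[0.35, 0.1, 1.0]])), Grid(np.array([[0.31, 0.5, 1.0]]))]
        out = refugium_map(maps, 0.3)
        np.testing.assert_array_equal(out.data, [[1.0, 0.0, 1.0]])

    def test_refugium_subset_of_each_period(self, rng):
        maps = [Grid(rng.uniform(size=(6, 6))) for _ in range(3)]
        refug = refugium_map(maps, 0.3).data.astype(bool)
        for g in maps:
            assert (refug <= (g.data >= 0.3)).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            refugium_map([Grid(np.zeros((2, 2))), Grid(np.zeros((3, 3)))])


class TestVariancePartition:
    def test_pure_time_variation(self):
        vals = np.zeros((3, 2, 3, 2, 2))
        for t in range(3):
            vals[:, :, t] = 0.2 + 0.3 * t
        part = variance_partition(_stack(vals))
        assert part.proportions["time"] == pytest.approx(1.0)
        assert part.proportions["aogcm"] == pytest.approx(0.0, abs=1e-12)

    def test_null_noise_matches_degrees_of_freedom_shares(self, rng):
        # i.i.d. noise splits SS in proportion to component df
        n_a, n_g, n_t = 13, 4, 3
        vals = rng.uniform(0.2, 0.8, size=(n_a, n_g, n_t, 20, 20))
        part = variance_partition(_stack(vals))
        n_layers = n_a * n_g * n_t
        df = {
            "time": n_t - 1,
            "aogcm": n_t * (n_g - 1),
            "algorithm": n_t * (n_a - 1),
            "residual": n_t * (n_a - 1) * (n_g - 1),
        }
        for key, d in df.items():
            assert part.proportions[key] == pytest.approx(d / (n_layers - 1), abs=0.02)

    def test_invariant_to_constant_shift(self, rng):
        vals = rng.uniform(0.1, 0.5, size=(3, 2, 3, 5, 5))
        p1 = variance_partition(_stack(vals)).proportions
        p2 = variance_partition(_stack(vals + 0.3)).proportions
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], abs=1e-9)

    def test_per_cell_proportions_sum_to_one(self, rng):
        vals = rng.uniform(size=(3, 2, 3, 4, 4))
        part = variance_partition(_stack(vals))
        total = sum(m.data for m in part.maps.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_missing_layer_rejected(self):
        vals = np.full((2, 2, 2, 2, 2), 0.5)
        vals[1, 0, 1] = np.nan
        st_ = _stack(vals)
        with pytest.raises(ValueError, match="missing layers"):
            variance_partition(st_)


class TestAssociation:
    def test_proportional_table_has_zero_chi2(self):
        res = classification_association([[10, 20], [5, 10]])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert res["p_chi2"] == pytest.approx(1.0)

    def test_diagonal_table(self):
        res = classification_association([[10, 0], [0, 10]])
        assert res["chi2"] == pytest.approx(20.0)
        assert res["df"] == 1

    def test_matches_hand_computation(self):
        # 2x2 table [[12,8],[6,14]]: E = [[9,11],[9,11]]
        table = np.array([[12, 8], [6, 14]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        g2 = 2 * (table * np.log(table / expected)).sum()
        res = classification_association(table)
        assert res["chi2"] == pytest.approx(chi2, abs=1e-9)
        assert res["G2"] == pytest.approx(g2, abs=1e-9)

    def test_zero_marginal_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = classification_association([[5, 5, 0], [5, 5, 0]])
        assert res["df"] == 1


class TestCentroid:
    def test_single_cell(self):
        data = np.zeros((4, 4))
        data[1, 2] = 0.9
        grid = Grid(data, xll=10.0, yll=20.0, cellsize=1.0)
        lon, lat = map_centroid(grid, 0.3)
        assert lon == pytest.approx(12.5)
        assert lat == pytest.approx(22.5)

    def test_two_cells_midpoint(self):
        data = np.zeros((1, 11))
        data[0, 0] = data[0, 10] = 1.0
        grid = Grid(data, xll=10.0, yll=0.0, cellsize=1.0)
        lon, lat = map_centroid(grid, 0.3)
        assert lon == pytest.approx(15.5)

    def test_symmetric_disc_centre(self):
        n = 21
        rr, cc = np.mgrid[0:n, 0:n]
        data = (((rr - 10) ** 2 + (cc - 10) ** 2) <= 36).astype(float)
        grid = Grid(data, xll=0.0, yll=0.0, cellsize=0.5)
        lon, lat = map_centroid(grid, 0.5)
        assert lon == pytest.approx(0.5 * 10.5, abs=0.5)
        assert lat == pytest.approx(0.5 * 10.5, abs=0.5)

    def test_no_suitable_cell_missing(self):
        lon, lat = map_centroid(Grid(np.zeros((2, 2))), 0.3)
        assert np.isnan(lon) and np.isnan(lat)


class TestPlantedDynamics:
    def test_planted_expansion_recovered_per_model(self):
        stack = gen_suitability_stack(
            SyntheticMapSpec(
                planted_dynamic="Expansion",
                n_algorithms=4,
                n_aogcms=2,
                var_time=0.4,
                var_aogcm=0.3,
                var_algorithm=0.2,
                var_noise=0.1,
                seed=1,
            )
        )
        dyn = classify_stack_dynamics(stack)
        frac = (dyn["label"] == RANGE_EXPANSION).mean()
        assert frac >= 0.95
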