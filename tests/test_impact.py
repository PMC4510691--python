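"""Cumulative impact engine: definition, oracle equivalence, invariants."""

import numpy as np
import pytest

from cumimpact import (
    Grid,
    HabitatLayer,
    NormalizedLayer,
    Raster,
    VulnerabilityMatrix,
    cumulative_impact,
    impact_oracle,
    stressor_contributions,
)
from conftest import random_instance


def _single_cell_instance():
    """One ocean cell hosting two habitats under two stressors.

    D = (0.5, 1.0), mu = [[1, 2], [0, 4]] gives per-habitat scores
    s = (1*0.5 + 2*1, 0*0.5 + 4*1) = (2.5, 4.0), hence mean 3.25, sum 6.5.
    """
    g = Grid(n_rows=1, n_cols=1, cell_size=1.0)
    stressors = [
        NormalizedLayer("s1", "t1", Raster(g, np.array([[0.5]]), "normalized"), 1.0),
        NormalizedLayer("s2", "t1", Raster(g, np.array([[1.0]]), "normalized"), 1.0),
    ]
    habitats = [
        HabitatLayer("h1", "nearshore_mixed", Raster(g, np.array([[1.0]]), "presence")),
        HabitatLayer("h2", "nearshore_mixed", Raster(g, np.array([[1.0]]), "presence")),
    ]
    weights = VulnerabilityMatrix.from_arrays(
        ["h1", "h2"], ["s1", "s2"], np.array([[1.0, 2.0], [0.0, 4.0]])
    )
    return stressors, habitats, weights


class TestDefinition:
    def test_hand_computed_mean_and_sum(self):
        stressors, habitats, weights = _single_cell_instance()
        mean = cumulative_impact(stressors, habitats, weights, mode="mean")
        total = cumulative_impact(stressors, habitats, weights, mode="sum")
        assert mean.raster.values[0, 0] == pytest.approx(3.25)
        assert total.raster.values[0, 0] == pytest.approx(6.5)

    def test_zero_stressors_give_zero_impact(self, grid):
        stressors = [
            NormalizedLayer("s1", "t1", Raster(grid, np.zeros(grid.shape), "normalized"), 0.0)
        ]
        habitats = [
            HabitatLayer("h1", "nearshore_mixed", Raster(grid, np.ones(grid.shape), "presence"))
        ]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1"], np.array([[3.0]]))
        out = cumulative_impact(stressors, habitats, weights)
        assert (out.raster.values == 0).all()

    def test_cell_without_habitat_is_nodata(self, grid):
        presence = np.ones(grid.shape)
        presence[0, 0] = 0.0
        stressors = [
            NormalizedLayer("s1", "t1", Raster(grid, np.full(grid.shape, 0.5), "normalized"), 1.0)
        ]
        habitats = [HabitatLayer("h1", "nearshore_mixed", Raster(grid, presence, "presence"))]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1"], np.array([[1.0]]))
        out = cumulative_impact(stressors, habitats, weights)
        assert not np.isfinite(out.raster.values[0, 0])
        assert np.isfinite(out.raster.values[1, 1])

    def test_nodata_stressor_propagates(self, grid):
        vals = np.full(grid.shape, 0.5)
        vals[2, 2] = np.nan
        stressors = [NormalizedLayer("s1", "t1", Raster(grid, vals, "normalized"), 1.0)]
        habitats = [HabitatLayer("h1", "nearshore_mixed", Raster(grid, np.ones(grid.shape), "presence"))]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1"], np.array([[1.0]]))
        out = cumulative_impact(stressors, habitats, weights)
        assert not np.isfinite(out.raster.values[2, 2])

    def test_mixed_periods_rejected(self, grid):
        r = Raster(grid, np.zeros(grid.shape), "normalized")
        stressors = [
            NormalizedLayer("s1", "t1", r, 1.0),
            NormalizedLayer("s2", "t2", r.copy(), 1.0),
        ]
        habitats = [HabitatLayer("h1", "nearshore_mixed", Raster(grid, np.ones(grid.shape), "presence"))]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1", "s2"], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="period"):
            cumulative_impact(stressors, habitats, weights)

    def test_unknown_stressor_rejected(self, grid):
        stressors = [
            NormalizedLayer("mystery", "t1", Raster(grid, np.zeros(grid.shape), "normalized"), 1.0)
        ]
        habitats = [HabitatLayer("h1", "nearshore_mixed", Raster(grid, np.ones(grid.shape), "presence"))]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1"], np.array([[1.0]]))
        with pytest.raises(KeyError, match="mystery"):
            cumulative_impact(stressors, habitats, weights)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("mode", ["mean", "sum"])
    def test_vectorized_matches_triple_loop(self, seed, mode):
        stressors, habitats, weights = random_instance(seed, max_side=16)
        fast = cumulative_impact(stressors, habitats, weights, mode=mode)
        slow = impact_oracle(stressors, habitats, weights, mode=mode)
        assert np.array_equal(fast.raster.valid_mask, slow.raster.valid_mask)
        diff = np.abs(fast.raster.values - slow.raster.values)
        assert np.nanmax(np.where(fast.raster.valid_mask, diff, 0.0)) < 1e-10

    def test_oracle_refuses_large_grids(self):
        g = Grid(n_rows=65, n_cols=10, cell_size=1.0)
        stressors = [NormalizedLayer("s1", "t1", Raster(g, np.zeros(g.shape), "normalized"), 1.0)]
        habitats = [HabitatLayer("h1", "nearshore_mixed", Raster(g, np.ones(g.shape), "presence"))]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="64"):
            impact_oracle(stressors, habitats, weights)


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nonnegative_and_mean_le_sum(self, seed):
        stressors, habitats, weights = random_instance(seed)
        mean = cumulative_impact(stressors, habitats, weights, mode="mean")
        total = cumulative_impact(stressors, habitats, weights, mode="sum")
        valid = mean.raster.valid_mask
        assert (mean.raster.values[valid] >= 0).all()
        assert (mean.raster.values[valid] <= total.raster.values[valid] + 1e-12).all()

    def test_modes_identical_on_single_habitat_cells(self, seed=4):
        stressors, habitats, weights = random_instance(seed, max_habitats=4)
        mean = cumulative_impact(stressors, habitats, weights, mode="mean")
        total = cumulative_impact(stressors, habitats, weights, mode="sum")
        stack = np.stack([h.raster.values for h in habitats])
        n_present = np.nansum(stack, axis=0)
        single = mean.raster.valid_mask & (n_present == 1)
        assert single.any()
        assert np.array_equal(mean.raster.values[single], total.raster.values[single])

    def test_upper_bound_by_max_habitat_weight_row_sum(self):
        stressors, habitats, weights = random_instance(7)
        mean = cumulative_impact(stressors, habitats, weights, mode="mean")
        bound = weights.weights.sum(axis=1).max()  # D_j <= 1
        valid = mean.raster.valid_mask
        assert (mean.raster.values[valid] <= bound + 1e-12).all()

    def test_monotone_in_stressor_intensity(self):
        stressors, habitats, weights = random_instance(8, nodata_frac=0.0)
        base = cumulative_impact(stressors, habitats, weights, mode="mean")
        bumped_vals = np.clip(stressors[0].raster.values + 0.2, 0, 1)
        bumped = [
            NormalizedLayer(
                stressors[0].stressor_id,
                "t1",
                stressors[0].raster.with_values(bumped_vals),
                stressors[0].reference_max,
            )
        ] + stressors[1:]
        higher = cumulative_impact(bumped, habitats, weights, mode="mean")
        valid = base.raster.valid_mask
        assert (higher.raster.values[valid] >= base.raster.values[valid] - 1e-12).all()

    def test_permutation_invariance(self):
        stressors, habitats, weights = random_instance(9)
        base = cumulative_impact(stressors, habitats, weights)
        rng = np.random.default_rng(0)
        sp = list(rng.permutation(len(stressors)))
        hp = list(rng.permutation(len(habitats)))
        shuffled = cumulative_impact(
            [stressors[j] for j in sp], [habitats[i] for i in hp], weights
        )
        assert np.allclose(base.raster.values, shuffled.raster.values, equal_nan=True)


class TestContributions:
    def test_additivity(self):
        stressors, habitats, weights = random_instance(12)
        full = cumulative_impact(stressors, habitats, weights)
        contribs = stressor_contributions(stressors, habitats, weights)
        total = np.sum([c.raster.values for c in contribs], axis=0)
        valid = full.raster.valid_mask
        assert np.allclose(total[valid], full.raster.values[valid], atol=1e-10)

    def test_single_stressor_contribution_is_the_map(self):
        stressors, habitats, weights = random_instance(13, max_stressors=1)
        full = cumulative_impact(stressors, habitats, weights)
        (contrib,) = stressor_contributions(stressors, habitats, weights)
        assert np.allclose(contrib.raster.values, full.raster.values, equal_nan=True)

    def test_zero_weight_column_gives_zero_contribution(self, grid):
        stressors = [
            NormalizedLayer("s1", "t1", Raster(grid, np.full(grid.shape, 0.8), "normalized"), 1.0),
            NormalizedLayer("s2", "t1", Raster(grid, np.full(grid.shape, 0.3), "normalized"), 1.0),
        ]
        habitats = [HabitatLayer("h1", "nearshore_mixed", Raster(grid, np.ones(grid.shape), "presence"))]
        weights = VulnerabilityMatrix.from_arrays(["h1"], ["s1", "s2"], np.array([[0.0, 2.0]]))
        contribs = stressor_contributions(stressors, habitats, weights)
        assert (contribs[0].raster.values == 0).all()
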