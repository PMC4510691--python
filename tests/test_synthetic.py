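"""Synthetic seascape generator: determinism, depth rules, structure."""

import numpy as np
import pytest

from cumimpact import SeascapeConfig, assert_aligned
from cumimpact.layers import DEEP_LIMIT_M, SHALLOW_LIMIT_M
from cumimpact.synthetic import (
    generate_bathymetry,
    generate_regions,
    generate_seascape,
    generate_stressors,
    generate_weight_matrix,
    ocean_mask,
)


class TestBathymetry:
    def test_all_depth_bands_nonempty(self, small_config):
        depth = generate_bathymetry(small_config).values
        ocean = depth > 0
        assert (ocean & (depth <= SHALLOW_LIMIT_M)).any()
        assert (ocean & (depth > SHALLOW_LIMIT_M) & (depth <= DEEP_LIMIT_M)).any()
        assert (depth > DEEP_LIMIT_M).any()
        assert (depth <= 0).any()  # some land with the default range

    def test_same_seed_identical(self, small_config):
        a = generate_bathymetry(small_config)
        b = generate_bathymetry(small_config)
        assert np.array_equal(a.values, b.values)

    def test_adjacent_seeds_differ(self):
        a = generate_bathymetry(SeascapeConfig(n_rows=20, n_cols=20, seed=5))
        b = generate_bathymetry(SeascapeConfig(n_rows=20, n_cols=20, seed=6))
        assert not np.array_equal(a.values, b.values)

    def test_degenerate_depth_range_rejected(self):
        cfg = SeascapeConfig(n_rows=10, n_cols=10, depth_range=(100.0, 100.0))
        with pytest.raises(ValueError, match="depth_range"):
            generate_bathymetry(cfg)

    def test_field_spans_requested_range(self, small_config):
        depth = generate_bathymetry(small_config).values
        lo, hi = small_config.depth_range
        assert depth.min() == pytest.approx(lo)
        assert depth.max() == pytest.approx(hi)


class TestStressors:
    def test_counts_and_flags(self, seascape):
        for period in ("t1", "t2"):
            assert len(seascape.stressors[period]) == 19
        comparable = [s for s in seascape.stressors["t1"] if s.comparable]
        assert len(comparable) == 12
        binary = [s for s in seascape.stressors["t1"] if s.is_binary]
        assert [s.stressor_id for s in binary] == ["benthic_structures"]

    def test_binary_layer_values(self, seascape):
        for period in ("t1", "t2"):
            layer = next(s for s in seascape.stressors[period] if s.is_binary)
            vals = layer.raster.valid_values()
            assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_nonnegative_and_land_masked(self, seascape):
        ocean = ocean_mask(seascape.bathymetry)
        for s in seascape.stressors["t1"]:
            assert np.nanmin(s.raster.values) >= 0
            assert np.isnan(s.raster.values[~ocean]).all()

    def test_trend_ratio_exact_with_zero_refresh(self):
        cfg = SeascapeConfig(n_rows=20, n_cols=20, seed=3, noise_refresh=0.0)
        bathy = generate_bathymetry(cfg)
        stacks = generate_stressors(cfg, bathy)
        for s1, s2, trend in zip(stacks["t1"], stacks["t2"], cfg.trend_per_stressor):
            if s1.is_binary:
                continue
            v1, v2 = s1.raster.values, s2.raster.values
            mask = np.isfinite(v1) & (v1 > 0)
            assert np.allclose(v2[mask] / v1[mask], trend)

    def test_unit_trend_zero_refresh_periods_identical(self):
        cfg = SeascapeConfig(
            n_rows=16, n_cols=16, seed=3, noise_refresh=0.0, trend_per_stressor=[1.0] * 19
        )
        stacks = generate_stressors(cfg, generate_bathymetry(cfg))
        for s1, s2 in zip(stacks["t1"], stacks["t2"]):
            assert s1.raster.equals(s2.raster)

    def test_negative_trend_rejected(self):
        with pytest.raises(ValueError, match="trend"):
            SeascapeConfig(n_rows=10, n_cols=10, trend_per_stressor=[-1.0] + [1.0] * 18)


class TestHabitats:
    def test_count(self, seascape):
        assert len(seascape.habitats) == 20

    def test_depth_rules_respected(self, seascape):
        depth = seascape.bathymetry.values
        for h in seascape.habitats:
            present = h.raster.values == 1
            if h.depth_class == "nearshore_mixed":
                assert (depth[present] <= SHALLOW_LIMIT_M).all()
            elif h.depth_class == "surface_pelagic":
                assert (depth[present] > SHALLOW_LIMIT_M).all()
            else:  # deep_pelagic, deep_benthic
                assert (depth[present] > DEEP_LIMIT_M).all()

    def test_every_ocean_cell_has_a_habitat(self, seascape):
        ocean = ocean_mask(seascape.bathymetry)
        stack = np.stack([h.raster.values for h in seascape.habitats])
        count = np.nansum(stack, axis=0)
        assert (count[ocean] >= 1).all()

    def test_some_cells_have_exactly_one_habitat(self, seascape):
        ocean = ocean_mask(seascape.bathymetry)
        stack = np.stack([h.raster.values for h in seascape.habitats])
        count = np.nansum(stack, axis=0)
        assert (count[ocean] == 1).any()

    def test_shallow_cell_hosts_no_deep_pelagic(self, seascape):
        depth = seascape.bathymetry.values
        shallow = (depth > 0) & (depth <= 30)
        if shallow.any():
            dp = next(h for h in seascape.habitats if h.depth_class == "deep_pelagic")
            assert (dp.raster.values[shallow] == 0).all()

    def test_deep_cell_can_host_three_depth_layers(self, seascape):
        """Below 200 m benthic, deep-pelagic and surface-pelagic layers coexist."""
        depth = seascape.bathymetry.values
        deep = depth > DEEP_LIMIT_M
        classes = {"surface_pelagic", "deep_pelagic", "deep_benthic"}
        per_class_any = {
            cls: np.any(
                np.stack(
                    [h.raster.values == 1 for h in seascape.habitats if h.depth_class == cls]
                ).any(axis=0)
                & deep
            )
            for cls in classes
        }
        assert all(per_class_any.values())

    def test_too_few_habitats_rejected(self):
        with pytest.raises(ValueError, match="habitat"):
            SeascapeConfig(n_rows=10, n_cols=10, n_habitats=3)


class TestRegions:
    def test_requested_label_count(self):
        cfg = SeascapeConfig(n_rows=50, n_cols=50, n_regions=5, seed=2)
        regions, table = generate_regions(cfg)
        labels = np.unique(regions.valid_values()).astype(int)
        assert len(labels) == 5
        assert set(labels) <= set(table["region_id"])

    def test_single_region_degenerate(self):
        cfg = SeascapeConfig(n_rows=10, n_cols=10, n_regions=1)
        regions, _ = generate_regions(cfg)
        assert set(np.unique(regions.valid_values())) == {1.0}

    def test_too_many_regions_rejected(self):
        cfg = SeascapeConfig(n_rows=4, n_cols=4, n_regions=17)
        with pytest.raises(ValueError, match="exceeds"):
            generate_regions(cfg)

    def test_land_masked_when_bathymetry_given(self, seascape):
        ocean = ocean_mask(seascape.bathymetry)
        assert np.isnan(seascape.regions.values[~ocean]).all()
        assert np.isfinite(seascape.regions.values[ocean]).all()


class TestWeightMatrix:
    def test_default_dimensions_match_registry(self, small_config):
        m = generate_weight_matrix(small_config)
        assert m.shape == (small_config.n_habitats, small_config.n_stressors)

    def test_raw_matrix_carries_nutrient_source_columns(self, small_config):
        raw = generate_weight_matrix(small_config, raw=True)
        assert "nutrient_oligotrophic" in raw.stressor_ids
        assert "nutrient_eutrophic" in raw.stressor_ids

    def test_weights_in_range_and_deterministic(self, small_config):
        a = generate_weight_matrix(small_config)
        b = generate_weight_matrix(small_config)
        assert a.weights.equals(b.weights)
        w = a.weights.to_numpy()
        assert (w >= 0).all() and (w <= 4).all()


class TestStructuralFidelity:
    def test_all_layers_aligned(self, seascape):
        rasters = [seascape.bathymetry, seascape.regions]
        rasters += [s.raster for s in seascape.stressors["t1"]]
        rasters += [s.raster for s in seascape.stressors["t2"]]
        rasters += [h.raster for h in seascape.habitats]
        assert_aligned(rasters)

    def test_full_seascape_deterministic(self):
        cfg = SeascapeConfig(n_rows=16, n_cols=16, seed=9)
        a = generate_seascape(cfg)
        b = generate_seascape(cfg)
        assert np.array_equal(a.bathymetry.values, b.bathymetry.values)
        for sa, sb in zip(a.stressors["t2"], b.stressors["t2"]):
            assert sa.raster.equals(sb.raster)
        assert a.weights.weights.equals(b.weights.weights)
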