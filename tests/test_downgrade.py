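"""The downgrading cascade: factors, bounds, and the AgDB-annual field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tundracap import (DowngradeConfig, GridLayer, LandscapeStack,
                       SyntheticConfig, carbon_to_total, compute_agdb_annual,
                       confidence_bounds, downgrade_factor_layer,
                       downgrade_stages, generate_stack, pixel_downgrade_factor)


def make_uniform_stack(agbc=1.0, se=0.0, cover=None, n=3):
    """Minimal hand-built stack: uniform biomass and cover, one zone."""
    cover = cover or {"forb": 1.0}
    shape = (n, n)
    full = {p: np.zeros(shape) for p in
            ("forb", "graminoid", "deciduous_shrub", "evergreen_shrub", "other")}
    for p, f in cover.items():
        full[p] = np.full(shape, f)
    return LandscapeStack(
        agbc_mean=GridLayer(np.full(shape, float(agbc)), "Mg C ha-1"),
        agbc_se=GridLayer(np.full(shape, float(se)), "Mg C ha-1"),
        cover={p: GridLayer(v, "fraction") for p, v in full.items()},
        zones=GridLayer(np.ones(shape, dtype=np.int32), "zone label"),
        zone_names={1: "only"},
    )


class TestCarbonToTotal:
    def test_carbon_biomass_factor(self):
        layer = GridLayer(np.array([[1.0, 0.0]]), "Mg C ha-1")
        out = carbon_to_total(layer, 2.03)
        assert out.values[0, 0] == pytest.approx(2.03)
        assert out.values[0, 1] == 0.0
        assert "C" not in out.units.split()

    def test_linear_scaling_on_grid(self):
        out = carbon_to_total(GridLayer(np.ones((3, 3)), "Mg C ha-1"), 2.03)
        assert out.values.sum() == pytest.approx(18.27)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            carbon_to_total(GridLayer(np.ones((2, 2)), "Mg C ha-1"), 0.0)


class TestConfidenceBounds:
    @pytest.mark.parametrize("mean, se, lcl, ucl", [
        (10.0, 0.0, 10.0, 10.0),
        (1.0, 2.0, 0.0, 4.92),     # lower limit clipped at zero
        (100.0, 10.0, 80.4, 119.6),
    ])
    def test_prediction_interval_arithmetic(self, mean, se, lcl, ucl):
        m = GridLayer(np.full((2, 2), mean), "Mg C ha-1")
        s = GridLayer(np.full((2, 2), se), "Mg C ha-1")
        lo, hi = confidence_bounds(m, s, 1.96)
        assert lo.values[0, 0] == pytest.approx(lcl)
        assert hi.values[0, 0] == pytest.approx(ucl)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confidence_bounds(GridLayer(np.ones((2, 2)), "x"),
                              GridLayer(np.ones((3, 3)), "x"))


class TestPixelDowngradeFactor:
    @pytest.mark.parametrize("cover, expected", [
        ({"forb": 1.0}, 0.8),
        ({"deciduous_shrub": 1.0}, 0.30),  # 0.6 digestibility x 0.5 preference
        ({"forb": 0.2, "graminoid": 0.3, "deciduous_shrub": 0.5}, 0.46),
        ({}, 0.0),
        ({"evergreen_shrub": 0.9, "other": 0.1}, 0.0),  # omitted types
    ])
    def test_cover_weighted_digestibility(self, cover, expected, config):
        assert pixel_downgrade_factor(cover, config) == pytest.approx(expected)

    def test_unknown_pft_ignored_with_warning(self, config, caplog):
        with caplog.at_level("WARNING"):
            out = pixel_downgrade_factor({"lichen": 0.5, "forb": 0.5}, config)
        assert out == pytest.approx(0.4)
        assert "lichen" in caplog.text

    @given(forb=st.floats(0, 0.4), gram=st.floats(0, 0.3), shrub=st.floats(0, 0.3))
    def test_factor_bounded_by_max_digestibility(self, forb, gram, shrub):
        f = pixel_downgrade_factor(
            {"forb": forb, "graminoid": gram, "deciduous_shrub": shrub},
            DowngradeConfig())
        assert 0.0 <= f <= 0.8


class TestComputeAgdbAnnual:
    def test_worked_pixel_full_forb(self, config):
        """1 Mg C/ha of pure forb -> 6.496 Mg/km2/yr of annual forage."""
        stack = make_uniform_stack(agbc=1.0, cover={"forb": 1.0})
        out = compute_agdb_annual(stack, config)
        assert out.values[0, 0] == pytest.approx(100 * 2.03 * 0.8 * 0.10 * 0.4)
        assert out.values[0, 0] == pytest.approx(6.496)

    def test_multiplication_order_is_immaterial(self, config):
        stack = make_uniform_stack(agbc=1.0, cover={"forb": 1.0})
        out = compute_agdb_annual(stack, config).values[0, 0]
        assert out == pytest.approx((((100 * 0.4) * 0.10) * 0.8) * 2.03, rel=1e-12)

    def test_zero_preferred_cover_gives_zero(self, config):
        stack = make_uniform_stack(agbc=5.0, cover={"evergreen_shrub": 0.9})
        assert (compute_agdb_annual(stack, config).values == 0).all()

    def test_missing_preferred_cover_layer_rejected(self, config):
        stack = make_uniform_stack()
        del stack.cover["graminoid"]
        with pytest.raises(ValueError, match="graminoid"):
            compute_agdb_annual(stack, config)

    def test_vectorized_equals_scalar_pixel_loop(self, config):
        """Oracle: an independent per-pixel scalar chain on a random stack."""
        stack = generate_stack(SyntheticConfig(n_rows=8, n_cols=8, seed=13))
        out = compute_agdb_annual(stack, config).values
        for i in range(8):
            for j in range(8):
                if stack.water_mask[i, j]:
                    expected = 0.0
                else:
                    cover = {p: float(l.values[i, j])
                             for p, l in stack.cover.items()}
                    expected = (float(stack.agbc_mean.values[i, j]) * 100
                                * config.carbon_to_biomass
                                * pixel_downgrade_factor(cover, config)
                                * config.forage_rate * config.npp_factor)
                assert out[i, j] == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_biomass_cover_and_factors(self):
        base = compute_agdb_annual(
            make_uniform_stack(1.0, cover={"forb": 0.3}), DowngradeConfig()
        ).values[0, 0]
        more_biomass = compute_agdb_annual(
            make_uniform_stack(2.0, cover={"forb": 0.3}), DowngradeConfig()
        ).values[0, 0]
        more_cover = compute_agdb_annual(
            make_uniform_stack(1.0, cover={"forb": 0.6}), DowngradeConfig()
        ).values[0, 0]
        higher_rate = compute_agdb_annual(
            make_uniform_stack(1.0, cover={"forb": 0.3}),
            DowngradeConfig(forage_rate=0.2)).values[0, 0]
        assert more_biomass > base
        assert more_cover > base
        assert higher_rate > base

    def test_biomass_variants_ordered(self, default_stack, config):
        lcl = compute_agdb_annual(default_stack, config, "lcl").values
        mean = compute_agdb_annual(default_stack, config, "mean").values
        ucl = compute_agdb_annual(default_stack, config, "ucl").values
        assert (lcl <= mean + 1e-12).all()
        assert (mean <= ucl + 1e-12).all()

    def test_water_is_true_zero_not_nodata(self, default_stack, config):
        out = compute_agdb_annual(default_stack, config)
        assert (out.values[default_stack.water_mask] == 0).all()
        assert not out.layer.nodata_mask[default_stack.water_mask].any()

    def test_nodata_propagates(self, config):
        stack = make_uniform_stack()
        stack.agbc_mean.nodata_mask[1, 1] = True
        out = compute_agdb_annual(stack, config)
        assert out.layer.nodata_mask[1, 1]
        assert not out.layer.nodata_mask[0, 0]


def test_stage_means_shrink_monotonically(default_stack, config):
    stages = downgrade_stages(default_stack, config)
    means = [stages[s].values.mean()
             for s in ("total_biomass", "digestible", "foraged", "annual")]
    assert means == sorted(means, reverse=True)


def test_factor_layer_matches_scalar_factor(default_stack, config):
    layer = downgrade_factor_layer(default_stack, config)
    i, j = 5, 7
    cover = {p: float(l.values[i, j]) for p, l in default_stack.cover.items()}
    assert layer.values[i, j] == pytest.approx(
        pixel_downgrade_factor(cover, config), abs=1e-10)


def test_config_validation():
    with pytest.raises(ValueError):
        DowngradeConfig(carbon_to_biomass=-1)
    with pytest.raises(ValueError):
        DowngradeConfig(digestibility={"forb": 0.8})
    with pytest.raises(ValueError):
        DowngradeConfig(forage_rate=0.0)
    with pytest.raises(ValueError):
        DowngradeConfig(agbc_units="stone acre-1")
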