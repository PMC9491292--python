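"""Category mapping, areas, site override and savannization."""

import numpy as np
import pytest
import xarray as xr

from hgdep import budgets, drydep, landsurface
from hgdep.species import HG0


class TestCategoryMapping:
    def test_mapping_is_total(self):
        mapping = landsurface.load_category_mapping()
        assert sorted(mapping.index) == list(range(73))
        assert set(mapping.values) <= set(drydep.CATEGORIES)

    def test_single_type_passes_through(self):
        src = np.zeros(73)
        src[17] = 1.0  # a deciduous-forest source type
        out = landsurface.map_categories(src)
        ci = list(drydep.CATEGORIES).index("deciduous_forest")
        assert out[ci] == 1.0 and out.sum() == 1.0

    def test_cofamily_types_add(self):
        src = np.zeros(73)
        src[17] = 0.3
        src[18] = 0.2  # maps to the same category as 17
        src[0] = 0.5   # water fills the rest
        out = landsurface.map_categories(src)
        ci = list(drydep.CATEGORIES).index("deciduous_forest")
        assert out[ci] == pytest.approx(0.5)

    def test_matches_scatter_add_oracle(self, rng):
        mapping = landsurface.load_category_mapping()
        src = rng.dirichlet(np.ones(73))
        out = landsurface.map_categories(src)
        expected = np.zeros(len(drydep.CATEGORIES))
        for t in range(73):
            expected[list(drydep.CATEGORIES).index(mapping.loc[t])] += src[t]
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            landsurface.map_categories(np.full(73, 0.1))


class TestCellArea:
    def test_sphere_partition_sums_to_surface_area(self):
        lat = -90 + (np.arange(18) + 0.5) * 10.0
        lon = -180 + (np.arange(36) + 0.5) * 10.0
        total = float(landsurface.grid_areas(lat, lon).sum())
        sphere = 4 * np.pi * landsurface.EARTH_RADIUS ** 2
        assert total == pytest.approx(sphere, rel=1e-6)

    def test_equatorial_cell_larger_than_polar(self):
        eq = landsurface.cell_area((-0.5, 0.5), (0, 1))
        polar = landsurface.cell_area((88.5, 89.5), (0, 1))
        assert eq > polar

    def test_one_degree_equator_closed_form(self):
        area = landsurface.cell_area((0.0, 1.0), (0.0, 1.0))
        expected = (landsurface.EARTH_RADIUS ** 2 * np.radians(1.0)
                    * (np.sin(np.radians(1.0)) - 0.0))
        assert area == pytest.approx(expected, rel=1e-12)


class TestSiteOverride:
    def test_pure_cell_idempotent_up_to_roughness_floor(self, surface):
        lat = float(surface.lat[1])
        lon = float(surface.lon[0])
        once = landsurface.site_override(surface, lat, lon,
                                         "coniferous_forest")
        twice = landsurface.site_override(once, lat, lon,
                                          "coniferous_forest")
        xr.testing.assert_identical(once, twice)

    def test_roughness_floor_semantics(self, surface):
        lat, lon = float(surface.lat[1]), float(surface.lon[0])
        ci = list(drydep.CATEGORIES).index("tundra")
        assert float(surface["z0"][ci, 1, 0]) < 1.0
        with pytest.warns(UserWarning):  # cell has no tundra LAI
            out = landsurface.site_override(surface, lat, lon, "tundra")
        assert float(out["z0"][ci, 1, 0]) == 1.0
        ci_rf = list(drydep.CATEGORIES).index("tropical_rainforest")
        out2 = landsurface.site_override(surface, float(surface.lat[3]),
                                         float(surface.lon[0]),
                                         "tropical_rainforest")
        assert float(out2["z0"][ci_rf, 3, 0]) == 2.0  # already above floor

    def test_coastal_override_raises_cell_velocity(self, met, surface,
                                                   table):
        # coastal column: mostly water; forcing 100% forest must raise vd
        lats = surface.lat.values
        i = int(np.argmin(np.abs(lats - 45.0)))
        j = surface.lon.size - 2
        cat = "deciduous_forest"
        assert float(surface["fraction"].sel(category="water")[i, j]) > 0.3
        over = landsurface.site_override(surface, float(lats[i]),
                                         float(surface.lon[j]), cat)
        sub = dict(time=slice(0, 48), lat=slice(i, i + 1),
                   lon=slice(j, j + 1))
        kw = dict(species=HG0, table=table)
        base = drydep.velocity_field(met.isel(**sub),
                                     surface.isel(lat=slice(i, i + 1),
                                                  lon=slice(j, j + 1)), **kw)
        new = drydep.velocity_field(met.isel(**sub),
                                    over.isel(lat=slice(i, i + 1),
                                              lon=slice(j, j + 1)), **kw)
        assert float(new.mean()) > float(base.mean())

    def test_missing_lai_falls_back_with_warning(self, surface):
        lat, lon = float(surface.lat[1]), float(surface.lon[0])
        with pytest.warns(UserWarning, match="category-default LAI"):
            out = landsurface.site_override(surface, lat, lon, "wetland")
        ci = list(drydep.CATEGORIES).index("wetland")
        i = 1
        assert (out["lai"][:, ci, i, 0]
                == landsurface.DEFAULT_LAI["wetland"]).all()

    def test_fractions_remain_normalised(self, surface):
        out = landsurface.site_override(surface, 0.0, 0.0,
                                        "tropical_rainforest")
        np.testing.assert_allclose(out["fraction"].sum("category").values,
                                   1.0, atol=1e-12)


class TestSavannize:
    def test_untouched_outside_mask(self, surface, rainforest_mask):
        out = landsurface.savannize(surface, rainforest_mask)
        m = rainforest_mask.values
        np.testing.assert_array_equal(
            out["fraction"].values[:, ~m], surface["fraction"].values[:, ~m])

    def test_pure_rainforest_cell_fully_swapped(self, surface,
                                                rainforest_mask):
        out = landsurface.savannize(surface, rainforest_mask)
        ci_rf = list(drydep.CATEGORIES).index("tropical_rainforest")
        ci_sv = list(drydep.CATEGORIES).index("grassland_savanna")
        m = rainforest_mask.values
        assert (out["fraction"].values[ci_rf][m] == 0.0).all()
        assert (out["fraction"].values[ci_sv][m]
                >= surface["fraction"].values[ci_rf][m]).all()
        np.testing.assert_allclose(out["fraction"].sum("category").values,
                                   1.0, atol=1e-9)

    def test_savanna_lai_is_reference_mean(self, surface, rainforest_mask):
        out = landsurface.savannize(surface, rainforest_mask)
        ci_sv = list(drydep.CATEGORIES).index("grassland_savanna")
        sav = surface["fraction"].values[ci_sv]
        ref = sav > 0
        w = sav[ref]
        expected = (surface["lai"].values[:, ci_sv][:, ref] * w).sum(1) / w.sum()
        m = rainforest_mask.values
        got = out["lai"].values[:, ci_sv][:, m]
        np.testing.assert_allclose(
            got, np.tile(expected[:, None], (1, got.shape[1])), rtol=1e-12)

    def test_no_reference_savanna_rejected(self, surface, rainforest_mask):
        bare = surface.copy(deep=True)
        ci_sv = list(drydep.CATEGORIES).index("grassland_savanna")
        frac = bare["fraction"].values
        frac[0] += frac[ci_sv]  # dump savanna coverage into deciduous
        frac[ci_sv] = 0.0
        with pytest.raises(ValueError, match="reference"):
            landsurface.savannize(bare, rainforest_mask)

    def test_velocity_drops_in_converted_cells(self, met, surface,
                                               rainforest_mask, table):
        out = landsurface.savannize(surface, rainforest_mask)
        sp = HG0.with_reactivity(3e-5)
        sub = dict(time=slice(0, 48))
        f0r = (rainforest_mask.values, "tropical_rainforest", 0.2)
        base = budgets.annual_mean_velocity(met.isel(**sub), surface, sp,
                                            table=table, f0_region=f0r)
        scen = budgets.annual_mean_velocity(met.isel(**sub), out, sp,
                                            table=table, f0_region=f0r)
        m = rainforest_mask.values
        assert ((scen.values - base.values)[m] < 0).all()
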