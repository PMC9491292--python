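"""Observation pipeline: flux arithmetic, STP correction, velocities,
group statistics, model comparison and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from hgdep import obs, synth


class TestFoliarUptake:
    def test_amazon_worked_example(self):
        # litterfall 49 + throughfall 72 - open-field wet deposition 18
        assert obs.foliar_uptake(49.0, 72.0, 18.0) == pytest.approx(103.0)

    def test_zero_fluxes(self):
        assert obs.foliar_uptake(0.0, 0.0, 0.0) == 0.0

    def test_negative_result_retained_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            assert obs.foliar_uptake(10.0, 5.0, 20.0) == pytest.approx(-5.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="throughfall"):
            obs.foliar_uptake(10.0, -1.0, 0.0)


class TestStpToLocal:
    def test_identity_at_stp(self):
        assert obs.stp_to_local(1.0, 273.0, 1.0) == pytest.approx(1.0)

    def test_warm_low_pressure_site(self):
        factor = obs.stp_to_local(1.0, 283.0, 0.65)
        assert factor == pytest.approx(273.0 / 283.0 * 0.65, rel=1e-12)
        assert 0.61 < factor < 0.97  # inside the plausible correction band

    def test_warm_sea_level_site(self):
        assert obs.stp_to_local(1.0, 293.6, 1.0) == pytest.approx(
            0.930, abs=5e-4)

    def test_never_increases_for_warm_subatmospheric(self, rng):
        t = rng.uniform(274.0, 310.0, 200)
        p = rng.uniform(0.5, 1.0, 200)
        assert (obs.stp_to_local(1.3, t, p) <= 1.3).all()


class TestVelocityFromFlux:
    def test_zero_flux(self):
        assert obs.velocity_from_flux(0.0, 1.0) == 0.0

    def test_amazon_upper_bound_value(self):
        # 103 ug m-2 yr-1 over 0.93 ng m-3 -> 0.351 cm/s
        v = obs.velocity_from_flux(103.0, 0.93)
        assert v == pytest.approx(103.0 / 3.1536e7 / 0.93e-3 * 100, rel=1e-12)
        assert v == pytest.approx(0.351, abs=5e-4)

    def test_small_flux_value(self):
        assert obs.velocity_from_flux(31.5, 1.0) == pytest.approx(0.0999,
                                                                  abs=5e-5)

    def test_round_trip_with_flux_from_velocity(self, rng):
        f = rng.uniform(1.0, 300.0, 50)
        c = rng.uniform(0.5, 3.0, 50)
        back = obs.flux_from_velocity(obs.velocity_from_flux(f, c), c)
        np.testing.assert_allclose(back, f, rtol=1e-12)


def _toy_db():
    return pd.DataFrame([
        dict(site_id="a", method="litterfall", litterfall_flux=30.0,
             throughfall_flux=np.nan, openfield_wetdep_flux=np.nan,
             hg0_conc_stp=1.5, local_temp=283.0, local_pressure=0.95),
        dict(site_id="b", method="total_foliar", litterfall_flux=49.0,
             throughfall_flux=72.0, openfield_wetdep_flux=18.0,
             hg0_conc_stp=1.0, local_temp=300.0, local_pressure=1.0),
        dict(site_id="c", method="litterfall", litterfall_flux=30.0,
             throughfall_flux=np.nan, openfield_wetdep_flux=np.nan,
             hg0_conc_stp=np.nan, local_temp=283.0, local_pressure=1.0),
        dict(site_id="d", method="total_foliar", litterfall_flux=1.0,
             throughfall_flux=1.0, openfield_wetdep_flux=30.0,
             hg0_conc_stp=1.0, local_temp=273.0, local_pressure=1.0),
    ])


class TestDeriveVelocities:
    def test_skips_missing_concentration(self):
        out = obs.derive_velocities(_toy_db())
        assert set(out["site_id"]) == {"a", "b", "d"}

    def test_applies_both_corrections(self):
        out = obs.derive_velocities(_toy_db()).set_index("site_id")
        c_local = obs.stp_to_local(1.5, 283.0, 0.95)
        assert out.loc["a", "v_dep"] == pytest.approx(
            obs.velocity_from_flux(30.0, c_local), rel=1e-12)
        assert out.loc["a", "correction_factor"] == pytest.approx(
            c_local / 1.5)

    def test_negative_foliar_uptake_flagged_not_dropped(self):
        out = obs.derive_velocities(_toy_db()).set_index("site_id")
        assert bool(out.loc["d", "negative_flux_flag"])
        assert out.loc["d", "flux"] == pytest.approx(-28.0)
        assert np.isnan(out.loc["d", "v_dep"])

    def test_deterministic(self):
        a = obs.derive_velocities(_toy_db())
        b = obs.derive_velocities(_toy_db())
        pd.testing.assert_frame_equal(a, b)


class TestGroupStats:
    def test_single_record_degenerate(self):
        df = pd.DataFrame({"method": ["litterfall"], "v_dep": [0.2]})
        out = obs.group_stats(df)
        assert out.loc["litterfall", "median"] == 0.2
        assert out.loc["litterfall", "q1"] == out.loc["litterfall", "q3"]
        assert out.loc["litterfall", "n"] == 1

    def test_type7_quartiles(self):
        df = pd.DataFrame({"method": ["m"] * 5, "v_dep": [1, 2, 3, 4, 5.0]})
        out = obs.group_stats(df)
        assert out.loc["m", "median"] == 3
        assert out.loc["m", "q1"] == 2  # linear-interpolation convention
        assert out.loc["m", "q3"] == 4

    def test_throughfall_addition_median_shift(self):
        # medians 0.028 -> 0.038 cm/s is a ~36% increase
        shift = (0.038 - 0.028) / 0.028 * 100
        assert shift == pytest.approx(35.7, abs=0.1)


class TestModelObsCompare:
    def test_identical_gives_unit_ratio(self):
        df = pd.DataFrame({"site_id": ["x"], "method": ["litterfall"],
                           "v_dep": [0.3]})
        out = obs.model_obs_compare(df, df)
        assert out["per_site"]["ratio_obs_model"].iloc[0] == 1.0
        assert out["per_site"]["bias"].iloc[0] == 0.0

    def test_flux_tower_style_underestimate(self):
        model = pd.DataFrame({"site_id": ["hf"], "method": ["micromet"],
                              "v_dep": [0.038]})
        observed = pd.DataFrame({"site_id": ["hf"], "method": ["micromet"],
                                 "v_dep": [0.072]})
        out = obs.model_obs_compare(model, observed)
        assert out["per_site"]["ratio_obs_model"].iloc[0] == pytest.approx(
            1.9, abs=0.05)

    def test_matches_elementwise_oracle(self, rng):
        n = 30
        model = pd.DataFrame({"site_id": np.arange(n), "method": "m",
                              "v_dep": rng.uniform(0.01, 0.5, n)})
        observed = pd.DataFrame({"site_id": np.arange(n), "method": "m",
                                 "v_dep": rng.uniform(0.01, 0.5, n)})
        out = obs.model_obs_compare(model, observed)["per_site"]
        np.testing.assert_allclose(
            out["ratio_obs_model"],
            observed["v_dep"].to_numpy() / model["v_dep"].to_numpy(),
            rtol=1e-12)

    def test_unmatched_ids_rejected(self):
        a = pd.DataFrame({"site_id": ["x"], "v_dep": [0.1]})
        b = pd.DataFrame({"site_id": ["y"], "v_dep": [0.1]})
        with pytest.raises(ValueError, match="matched"):
            obs.model_obs_compare(a, b)


class TestParameterRecovery:
    def test_median_recovers_truth_within_ten_percent(self, surface, conc,
                                                      synth_cfg):
        # 50 sites, lognormal sigma 0.3 around a uniform 0.35 cm/s truth
        import xarray as xr
        truth = 0.35
        v = xr.DataArray(np.full((8, 8), truth),
                         coords={"lat": surface.lat, "lon": surface.lon},
                         dims=("lat", "lon"))
        db = synth.generate_site_db(v, conc, synth_cfg)
        vel = obs.derive_velocities(db)
        stats = obs.group_stats(vel, by=("method",))
        got = stats.loc["total_foliar", "median"]
        assert abs(got - truth) / truth < 0.10

    def test_litterfall_undersamples_by_design(self, surface, conc,
                                               synth_cfg):
        import xarray as xr
        v = xr.DataArray(np.full((8, 8), 0.35),
                         coords={"lat": surface.lat, "lon": surface.lon},
                         dims=("lat", "lon"))
        db = synth.generate_site_db(v, conc, synth_cfg)
        stats = obs.group_stats(obs.derive_velocities(db), by=("method",))
        ratio = (stats.loc["total_foliar", "median"]
                 / stats.loc["litterfall", "median"])
        assert ratio == pytest.approx(1.0 / synth_cfg.litterfall_fraction,
                                      rel=1e-9)
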