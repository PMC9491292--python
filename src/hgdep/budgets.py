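"""Deposition-flux maps, regional budgets and land-cover-change deltas.

Given an annual-mean deposition-velocity field and a prescribed Hg0
concentration field, the deposition flux is F = v C (the same relation,
inverted, that turns site flux measurements into velocities).  Budgets are
area integrals in Mg/yr.  Concentration fields are inputs here — nothing
is transported — so scenario deltas quantify the bookkeeping of a changed
land sink at fixed concentrations, with an optional box-model step that
re-equilibrates the global burden to the changed sink.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import xarray as xr

from hgdep import drydep
from hgdep.boxmodel import BoxModelConfig, budget_report, steady_state
from hgdep.obs import SECONDS_PER_YEAR
from hgdep.species import SpeciesParams

UG_PER_MG = 1e12
G_PER_MG = 1e6


def deposition_flux(v_cms, conc_ngm3):
    """Deposition flux (ug m-2 yr-1) from v (cm s-1) and C (ng m-3)."""
    v = np.asarray(v_cms, dtype=float)
    c = np.asarray(conc_ngm3, dtype=float)
    if np.any(v < 0) or np.any(c < 0):
        raise ValueError("velocity and concentration must be >= 0")
    out = v / 100.0 * c * 1e-3 * SECONDS_PER_YEAR
    if isinstance(v_cms, xr.DataArray):
        out = xr.DataArray(out, coords=v_cms.coords, dims=v_cms.dims,
                           name="deposition_flux",
                           attrs={"units": "ug m-2 yr-1"})
    return out


def regional_budget(flux_ugm2yr, area_m2, mask=None) -> float:
    """Area-integrated deposition over a region, Mg/yr."""
    f = np.asarray(flux_ugm2yr, dtype=float)
    a = np.asarray(area_m2, dtype=float)
    if mask is not None:
        m = np.asarray(mask.values if hasattr(mask, "values") else mask,
                       dtype=bool)
        if m.shape != f.shape:
            raise ValueError("mask is not aligned with the flux grid")
        f = np.where(m, f, 0.0)
    return float((f * a).sum() / UG_PER_MG)


def annual_mean_velocity(met: xr.Dataset, surface: xr.Dataset,
                         species: SpeciesParams, **kwargs) -> xr.DataArray:
    """Time-mean deposition-velocity map in cm s-1."""
    vd = drydep.velocity_field(met, surface, species, **kwargs)
    out = vd.mean("time") * 100.0
    out.attrs.update(units="cm s-1", species=species.name)
    return out


def scenario_delta(base_surface: xr.Dataset, scenario_surface: xr.Dataset,
                   met: xr.Dataset, species: SpeciesParams,
                   conc_ngm3, region_mask=None,
                   box_config: BoxModelConfig | None = None,
                   scenario_box: str = "tropics", **kwargs) -> dict:
    """Deposition-budget change between two land surfaces.

    Both surfaces are run through the velocity model under the same
    meteorology and species settings; budgets use the fixed concentration
    field.  Returns per-cell velocity/flux deltas plus land and region
    totals (Mg/yr).  If ``box_config`` is given, the relative change in the
    land sink is applied to the Hg0 deposition rate of ``scenario_box`` and
    the box model re-equilibrated, yielding the shift of deposition to the
    remaining (ocean and other-box) sinks.
    """
    area = base_surface["area"]
    out = {}
    land_frac = {}
    for tag, surf in (("base", base_surface), ("scenario", scenario_surface)):
        vd = annual_mean_velocity(met, surf, species, **kwargs)
        flux = deposition_flux(vd, conc_ngm3)
        water = surf["fraction"].sel(category="water").values
        land = water < 1.0
        land_frac[tag] = land
        out[f"{tag}_velocity"] = vd
        out[f"{tag}_flux"] = flux
        out[f"{tag}_land_budget"] = regional_budget(flux, area, land)
        if region_mask is not None:
            out[f"{tag}_region_budget"] = regional_budget(flux, area,
                                                          region_mask)
    out["delta_velocity"] = out["scenario_velocity"] - out["base_velocity"]
    out["delta_flux"] = out["scenario_flux"] - out["base_flux"]
    out["delta_land_budget"] = (out["scenario_land_budget"]
                                - out["base_land_budget"])
    if region_mask is not None:
        out["delta_region_budget"] = (out["scenario_region_budget"]
                                      - out["base_region_budget"])

    if box_config is not None and out["base_land_budget"] > 0:
        out.update(_box_adjustment(box_config, scenario_box,
                                   out["scenario_land_budget"]
                                   / out["base_land_budget"]))
    return out


def _box_adjustment(config: BoxModelConfig, box: str, sink_scale: float
                    ) -> dict:
    """Re-equilibrate the box model with one box's Hg0 sink rescaled.

    The scenario's land-sink ratio rescales the Hg0 deposition rate of the
    chosen box; at the new steady state the total deposition still equals
    total emissions, so whatever the weakened land sink no longer removes
    is transferred to the other deposition pathways (ocean and other
    regions).
    """
    i = config.index(box)
    kd0 = list(config.k_dep_hg0)
    kd0[i] *= sink_scale
    scen = dataclasses.replace(config, k_dep_hg0=tuple(kd0))

    base_rep = budget_report(steady_state(config), config)
    scen_rep = budget_report(steady_state(scen), scen)

    def _outside_sink(rep, cfg):
        dep = rep["hg0_dry_deposition"] + rep["hg2_deposition"] \
            - rep["prompt_reemission"]
        return float(dep.sum() - dep.loc[box]), float(dep.loc[box])

    base_other, base_box = _outside_sink(base_rep, config)
    scen_other, scen_box = _outside_sink(scen_rep, scen)
    return {
        "box_base_burden_hg0": float(steady_state(config).hg0.sum()),
        "box_scenario_burden_hg0": float(steady_state(scen).hg0.sum()),
        "box_delta_deposition_outside": scen_other - base_other,
        "box_delta_deposition_in_region": scen_box - base_box,
    }


def soil_source_scaling(per_area_emission_g_ha, deforestation_rate_ha_yr
                        ) -> float:
    """Post-deforestation soil Hg source, Mg/yr, from a per-area emission
    (g ha-1) and a deforestation rate (ha/yr)."""
    e = float(per_area_emission_g_ha)
    r = float(deforestation_rate_ha_yr)
    if e < 0 or r < 0:
        raise ValueError("emission and deforestation rate must be >= 0")
    return e * r / G_PER_MG
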