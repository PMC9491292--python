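"""Synthetic inputs with the statistical structure the analysis assumes.

Generators here emulate the *shape* of the real forcing data — diurnal and
seasonal meteorology, weekly LAI cycles per land category, mixed and
coastal grid cells with an Amazon-like rainforest block and a savanna
reference block, and site flux records with multiplicative lognormal noise
around a known true deposition velocity — without any geographic realism
or spatial covariance.  Every generator is deterministic for a fixed seed
(numpy PCG64 via ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from hgdep.drydep import CATEGORIES
from hgdep.landsurface import grid_areas
from hgdep.obs import SECONDS_PER_YEAR, stp_to_local

#: Seed of the fixed "paper-like" regression fixture.
FIXTURE_SEED = 20150101

SOLAR_CONSTANT_SURFACE = 1000.0  # clear-sky max surface shortwave, W m-2

#: Weekly-LAI cycle parameters per category: (annual mean, seasonal
#: amplitude).  Rainforest is evergreen; deciduous forest swings hard.
LAI_CYCLE = {
    "deciduous_forest": (3.0, 2.5), "coniferous_forest": (4.0, 1.0),
    "tropical_rainforest": (5.5, 0.5), "agricultural": (2.0, 1.8),
    "grassland_savanna": (1.5, 1.0), "shrubland": (1.0, 0.5),
    "tundra": (0.5, 0.45), "desert_barren": (0.05, 0.0),
    "wetland": (2.0, 1.5), "urban": (0.5, 0.3), "water": (0.0, 0.0),
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic world (defaults are the study conditions)."""

    nlat: int = 10
    nlon: int = 10
    hours: int = 24 * 14
    n_sites: int = 50
    noise_sigma: float = 0.3          # lognormal sigma on site fluxes
    litterfall_fraction: float = 0.73  # of total foliar uptake
    wetdep_fraction: float = 0.15      # open-field wet dep vs total uptake
    mean_temp: float = 288.0           # K, global annual mean
    diurnal_temp_amp: float = 5.0      # K
    seasonal_temp_amp: float = 10.0    # K, extratropics
    ustar_mean: float = 0.35           # m s-1
    conc_mean: float = 1.3             # ng m-3 Hg0 at STP
    seed: int = FIXTURE_SEED

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _axes(nlat: int, nlon: int):
    lat = -90 + (np.arange(nlat) + 0.5) * 180.0 / nlat
    lon = -180 + (np.arange(nlon) + 0.5) * 360.0 / nlon
    return lat, lon


def solar_radiation(times, lat, lon, cloud_fraction=0.0):
    """Clear-sky-scaled surface shortwave from solar geometry, W m-2.

    Uses the solar declination and the local solar hour angle from
    longitude, so cells at local midnight get exactly zero.  Shape
    (time, lat, lon).
    """
    idx = pd.DatetimeIndex(np.asarray(times))
    doy = idx.dayofyear.to_numpy()
    hour_utc = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    decl = np.radians(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.0))
    lat_r = np.radians(np.asarray(lat, dtype=float))
    hour_local = hour_utc[:, None] + np.asarray(lon, dtype=float)[None, :] / 15.0
    hour_angle = np.radians((hour_local % 24.0 - 12.0) * 15.0)
    cosz = (np.sin(lat_r)[None, :, None] * np.sin(decl)[:, None, None]
            + np.cos(lat_r)[None, :, None] * np.cos(decl)[:, None, None]
            * np.cos(hour_angle)[:, None, :])
    srad = SOLAR_CONSTANT_SURFACE * np.clip(cosz, 0.0, None)
    return srad * (1.0 - 0.75 * np.asarray(cloud_fraction) ** 3)


def generate_met(config: SynthConfig | None = None, seed: int | None = None,
                 start: str = "2015-01-01") -> xr.Dataset:
    """Hourly gridded meteorology: temperature with seasonal + diurnal
    cycles, geometry-driven solar radiation, positive friction velocity,
    cloud fraction, pressure, and neutral stability."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lat, lon = _axes(cfg.nlat, cfg.nlon)
    times = pd.date_range(start, periods=cfg.hours, freq="h")
    shape = (cfg.hours, cfg.nlat, cfg.nlon)

    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy()
    lat_w = np.cos(np.radians(lat))  # warm equator, cold poles
    base = cfg.mean_temp - 25.0 + 33.0 * lat_w
    seasonal = (cfg.seasonal_temp_amp * (1 - lat_w[None, :])
                * np.sign(lat)[None, :]
                * -np.cos(2 * np.pi * (doy[:, None] - 15) / 365.0))
    diurnal = (cfg.diurnal_temp_amp
               * -np.cos(2 * np.pi
                         * (hour[:, None, None] + lon[None, None, :] / 15.0
                            - 14.0) / 24.0))
    temp = (base[None, :, None] + seasonal[:, :, None] + diurnal
            + rng.normal(0, 1.0, shape))

    cloud = np.clip(rng.beta(2.0, 3.0, shape), 0.0, 1.0)
    srad = solar_radiation(times, lat, lon, cloud)
    ustar = rng.lognormal(np.log(cfg.ustar_mean), 0.35, shape)
    pressure = np.full(shape, 101325.0) + rng.normal(0, 200.0, shape)

    return xr.Dataset(
        {
            "air_temp": (("time", "lat", "lon"), temp),
            "surface_temp": (("time", "lat", "lon"),
                             temp + 1.5 * srad / SOLAR_CONSTANT_SURFACE),
            "friction_velocity": (("time", "lat", "lon"), ustar),
            "wind_speed_10m": (("time", "lat", "lon"), ustar / 0.07),
            "solar_radiation": (("time", "lat", "lon"), srad),
            "cloud_fraction": (("time", "lat", "lon"), cloud),
            "pressure": (("time", "lat", "lon"), pressure),
            "stability_param": (("time", "lat", "lon"), np.zeros(shape)),
        },
        coords={"time": times, "lat": lat, "lon": lon},
        attrs={"title": "synthetic hourly meteorology"},
    )


def _weekly_lai(lat: np.ndarray) -> np.ndarray:
    """Weekly LAI (week, category, lat, lon-ready) per category."""
    weeks = np.arange(52)
    phase = np.cos(2 * np.pi * (weeks - 29) / 52.0)  # peak ~late July (NH)
    out = np.zeros((52, len(CATEGORIES), lat.size))
    for ci, cat in enumerate(CATEGORIES):
        mean, amp = LAI_CYCLE[cat]
        nh = mean + amp * phase
        sh = mean - amp * phase
        tropics = np.full(52, mean + 0.5 * amp)
        for li, la in enumerate(lat):
            if abs(la) < 23.5:
                out[:, ci, li] = tropics
            elif la >= 0:
                out[:, ci, li] = nh
            else:
                out[:, ci, li] = sh
    return np.clip(out, 0.0, None)


def generate_surface(config: SynthConfig | None = None,
                     seed: int | None = None) -> xr.Dataset:
    """Land-surface map with mixed cells, a coastal water strip, an
    Amazon-like rainforest block (masked), a savanna reference block, and
    at least one cell of every category."""
    from hgdep.drydep import LandCategoryTable

    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lat, lon = _axes(cfg.nlat, cfg.nlon)
    nc = len(CATEGORIES)
    ci = {c: i for i, c in enumerate(CATEGORIES)}

    frac = np.zeros((nc, cfg.nlat, cfg.nlon))
    rainforest_mask = np.zeros((cfg.nlat, cfg.nlon), dtype=bool)
    tropics = np.abs(lat) < 23.5
    mid = ~tropics & (np.abs(lat) < 66.0)

    for i in range(cfg.nlat):
        for j in range(cfg.nlon):
            if j == cfg.nlon - 1:  # eastern ocean strip
                frac[ci["water"], i, j] = 1.0
            elif j == cfg.nlon - 2:  # coastal mix
                w = rng.uniform(0.4, 0.8)
                frac[ci["water"], i, j] = w
                land = ("tropical_rainforest" if tropics[i]
                        else "deciduous_forest" if mid[i] else "tundra")
                frac[ci[land], i, j] = 1.0 - w
                if tropics[i]:
                    rainforest_mask[i, j] = True
            elif tropics[i] and j < cfg.nlon // 2:  # Amazon-like block
                r = rng.uniform(0.8, 1.0)
                frac[ci["tropical_rainforest"], i, j] = r
                frac[ci["wetland"], i, j] = 1.0 - r
                rainforest_mask[i, j] = True
            elif tropics[i]:  # savanna reference block
                s = rng.uniform(0.7, 1.0)
                frac[ci["grassland_savanna"], i, j] = s
                frac[ci["shrubland"], i, j] = 1.0 - s
            elif mid[i]:  # temperate mosaic
                w3 = rng.dirichlet((4.0, 2.0, 2.0))
                for k, cat in enumerate(("deciduous_forest",
                                         "coniferous_forest",
                                         "agricultural")):
                    frac[ci[cat], i, j] = w3[k]
            else:  # high latitudes
                w2 = rng.dirichlet((3.0, 1.0))
                frac[ci["tundra"], i, j] = w2[0]
                frac[ci["coniferous_forest"], i, j] = w2[1]

    # guarantee every category appears somewhere
    interior = [(i, j) for i in range(cfg.nlat) for j in range(cfg.nlon - 2)]
    for k, cat in enumerate(CATEGORIES):
        if not np.any(frac[ci[cat]] > 0):
            i, j = interior[k % len(interior)]
            frac[:, i, j] = 0.0
            frac[ci[cat], i, j] = 1.0
            rainforest_mask[i, j] = cat == "tropical_rainforest"

    lai_lat = _weekly_lai(lat)  # (week, category, lat)
    lai = np.repeat(lai_lat[:, :, :, None], cfg.nlon, axis=3)
    lai *= np.where(frac[None, :, :, :] > 0, 1.0, 0.0)

    table = LandCategoryTable.default()
    z0 = np.repeat(
        np.repeat(table.z0.reindex(list(CATEGORIES)).to_numpy()
                  [:, None, None], cfg.nlat, axis=1), cfg.nlon, axis=2)

    return xr.Dataset(
        {
            "fraction": (("category", "lat", "lon"), frac),
            "lai": (("week", "category", "lat", "lon"), lai),
            "z0": (("category", "lat", "lon"), z0),
            "area": grid_areas(lat, lon),
            "rainforest_mask": (("lat", "lon"), rainforest_mask),
        },
        coords={"category": list(CATEGORIES), "lat": lat, "lon": lon,
                "week": np.arange(52)},
        attrs={"title": "synthetic land surface"},
    )


def generate_concentration(surface: xr.Dataset,
                           config: SynthConfig | None = None) -> xr.DataArray:
    """Smooth Hg0 surface-concentration field at STP, ng m-3 (NH-high
    interhemispheric gradient, no noise)."""
    cfg = config or SynthConfig()
    lat = surface["lat"].values
    conc = cfg.conc_mean + 0.15 * np.sin(np.radians(lat))
    field = np.repeat(conc[:, None], surface["lon"].size, axis=1)
    return xr.DataArray(field, coords={"lat": lat,
                                       "lon": surface["lon"].values},
                        dims=("lat", "lon"), name="hg0_conc_stp",
                        attrs={"units": "ng m-3", "reference": "STP"})


def generate_site_db(true_velocity_cms: xr.DataArray,
                     conc_stp: xr.DataArray,
                     config: SynthConfig | None = None,
                     seed: int | None = None,
                     forest_mask=None) -> pd.DataFrame:
    """Site flux records around a known true deposition velocity.

    Each sampled site yields a ``litterfall`` row and a ``total_foliar``
    row.  The site's true total foliar uptake flux is v_true * C_local *
    one year, perturbed by multiplicative lognormal noise of sigma
    ``noise_sigma``; litterfall carries a fixed fraction of the total
    (woody-tissue and wash-off pathways are invisible to litterfall
    collection), and throughfall closes the balance against the open-field
    wet-deposition flux.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    v = np.asarray(true_velocity_cms.values, dtype=float)
    lat = true_velocity_cms["lat"].values
    lon = true_velocity_cms["lon"].values

    ok = v > 1e-4
    if forest_mask is not None:
        ok &= np.asarray(forest_mask, dtype=bool)
    cells = np.argwhere(ok)
    if cells.size == 0:
        raise ValueError("no usable cells for site placement")
    picks = cells[rng.integers(0, len(cells), cfg.n_sites)]

    rows = []
    for s, (i, j) in enumerate(picks):
        t_local = cfg.mean_temp + rng.normal(0, 5.0)
        p_local = np.clip(1.0 - rng.uniform(0, 0.2), 0.05, None)
        c_stp = float(conc_stp.values[i, j])
        c_local = stp_to_local(c_stp, t_local, p_local)
        noise = rng.lognormal(0.0, cfg.noise_sigma) if cfg.noise_sigma else 1.0
        total = v[i, j] / 100.0 * (c_local * 1e-3) * SECONDS_PER_YEAR * noise
        wetdep = cfg.wetdep_fraction * total
        litterfall = cfg.litterfall_fraction * total
        throughfall = total - litterfall + wetdep
        common = dict(site_id=f"S{s:03d}", lat=lat[i], lon=lon[j],
                      elevation_m=float(rng.uniform(0, 800)), year=2015,
                      land_class="tropical_rainforest"
                      if abs(lat[i]) < 23.5 else "deciduous_forest",
                      amazon=bool(abs(lat[i]) < 23.5),
                      litterfall_flux=litterfall,
                      throughfall_flux=throughfall,
                      openfield_wetdep_flux=wetdep,
                      net_exchange_flux=np.nan,
                      hg0_conc_stp=c_stp, local_temp=t_local,
                      local_pressure=p_local)
        rows.append({**common, "method": "litterfall"})
        rows.append({**common, "method": "total_foliar"})
    return pd.DataFrame(rows)


def write_netcdf(ds, path) -> None:
    """Write a dataset with the scipy NetCDF3 engine (bool vars cast)."""
    ds = ds.copy()
    if hasattr(ds, "data_vars"):
        for name, var in ds.data_vars.items():
            if var.dtype == bool:
                ds[name] = var.astype("i1")
    ds.to_netcdf(path, engine="scipy")


def generate_all(outdir, config: SynthConfig | None = None) -> dict:
    """Write the full synthetic input set (met, surface, concentration,
    site database) under ``outdir``; returns the paths."""
    import pathlib

    from hgdep.budgets import annual_mean_velocity
    from hgdep.species import HG0

    cfg = config or SynthConfig()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    met = generate_met(cfg)
    surface = generate_surface(cfg)
    conc = generate_concentration(surface, cfg)
    vd = annual_mean_velocity(met, surface, HG0)
    sites = generate_site_db(vd, conc, cfg)

    paths = {"met": outdir / "met.nc", "surface": outdir / "surface.nc",
             "conc": outdir / "conc.nc", "sites": outdir / "sites.csv"}
    write_netcdf(met, paths["met"])
    write_netcdf(surface, paths["surface"])
    write_netcdf(conc.to_dataset(), paths["conc"])
    sites.to_csv(paths["sites"], index=False)
    return paths
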