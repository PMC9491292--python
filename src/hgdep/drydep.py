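"""Hourly dry-deposition velocities over a gridded land surface.

Combines the resistance primitives in :mod:`hgdep.resistances` with a
seasonal baseline-resistance table per land category.  A grid cell may mix
several land categories; the velocity is evaluated separately per category
and averaged with area-fraction weighting.  Over water the resistance
scheme is not applied (Hg0 air–sea exchange is a separate process); an
externally supplied constant ocean velocity is used instead (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from hgdep import resistances as rs
from hgdep.species import SpeciesParams

#: The 11 dry-deposition land categories.
CATEGORIES = (
    "deciduous_forest",
    "coniferous_forest",
    "tropical_rainforest",
    "agricultural",
    "grassland_savanna",
    "shrubland",
    "tundra",
    "desert_barren",
    "wetland",
    "urban",
    "water",
)

WATER = "water"
SEASONS = (1, 2, 3, 4, 5)

#: Month -> seasonal class in the Northern Hemisphere extratropics
#: (1 midsummer, 2 autumn, 3 late autumn, 4 winter, 5 spring transition).
#: The Southern Hemisphere shifts months by six; the tropics (|lat| < 23.5)
#: are class 1 year-round.  Overridable per run via ``season_of_time``.
NH_MONTH_SEASON = {1: 4, 2: 4, 3: 5, 4: 5, 5: 5, 6: 1, 7: 1, 8: 1,
                   9: 2, 10: 2, 11: 3, 12: 4}

TROPICS_LAT = 23.5


@dataclass
class MetRecord:
    """One hour of meteorological drivers at a point.

    Temperatures in K, friction velocity and wind in m s-1, radiation in
    W m-2, pressure in Pa; ``stability_param`` is the Monin–Obukhov
    zeta = zref/L (0 = neutral).
    """

    air_temp: float
    surface_temp: float
    friction_velocity: float
    wind_speed_10m: float = 5.0
    solar_radiation: float = 0.0
    cloud_fraction: float = 0.0
    pressure: float = 101325.0
    stability_param: float = 0.0
    timestamp: object = None

    def __post_init__(self):
        if self.air_temp <= 0:
            raise ValueError(f"air_temp must be > 0 K, got {self.air_temp}")
        if self.friction_velocity < 0:
            raise ValueError(
                f"friction_velocity must be >= 0, got {self.friction_velocity}")
        if self.solar_radiation < 0:
            raise ValueError(
                f"solar_radiation must be >= 0, got {self.solar_radiation}")
        if not 0 <= self.cloud_fraction <= 1:
            raise ValueError(
                f"cloud_fraction must be in [0, 1], got {self.cloud_fraction}")


class LandCategoryTable:
    """Seasonal baseline resistances and default roughness per category."""

    def __init__(self, table: pd.DataFrame, z0: pd.Series):
        missing = set(CATEGORIES) - set(table.index.get_level_values(0))
        if missing:
            raise ValueError(f"resistance table missing categories: {missing}")
        for cat in CATEGORIES:
            seasons = set(table.loc[cat].index)
            if seasons != set(SEASONS):
                raise ValueError(
                    f"category {cat!r} has seasons {sorted(seasons)}, need 1..5")
        self.table = table
        self.z0 = z0

    @classmethod
    def default(cls) -> "LandCategoryTable":
        pkg = resources.files("hgdep.data")
        with (pkg / "baseline_resistances.csv").open() as fh:
            tab = pd.read_csv(fh, comment="#").set_index(["category", "season"])
        with (pkg / "category_z0.csv").open() as fh:
            z0 = pd.read_csv(fh, comment="#").set_index("category")["z0"]
        return cls(tab, z0)

    def row(self, category: str, season: int) -> pd.Series:
        if season not in SEASONS:
            raise ValueError(f"season must be in 1..5, got {season}")
        return self.table.loc[(category, season)]

    def rows(self, category: str, season):
        """Vectorised lookup: per-element baseline values for a season array."""
        season = np.asarray(season)
        if not np.isin(season, SEASONS).all():
            raise ValueError("season indices must be in 1..5")
        sub = self.table.loc[category].reindex(SEASONS)
        return {col: sub[col].to_numpy()[season - 1] for col in sub.columns}


def season_of_time(times, lat):
    """Seasonal class (1..5) for each (time, lat) pair.

    ``times`` is a datetime64 array, ``lat`` in degrees.  Broadcasts to
    shape (time, lat).
    """
    months = pd.DatetimeIndex(np.asarray(times).ravel()).month.to_numpy()
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    nh = np.array([NH_MONTH_SEASON[m] for m in months])
    sh = np.array([NH_MONTH_SEASON[(m + 5) % 12 + 1] for m in months])
    season = np.where(lat[None, :] >= 0, nh[:, None], sh[:, None])
    season = np.where(np.abs(lat)[None, :] < TROPICS_LAT, 1, season)
    return season


def point_resistances(met: MetRecord, baselines, lai: float, z0: float,
                      species: SpeciesParams, zref: float = 10.0
                      ) -> rs.ResistanceSet:
    """Evaluate the full resistance set for one category at one point/hour."""
    ra = rs.aerodynamic_resistance(met.friction_velocity, z0, zref,
                                   met.stability_param)
    rb = rs.boundary_resistance(met.friction_velocity, species)
    stom = rs.stomatal_mesophyll_resistance(
        baselines["ri"], met.solar_radiation, met.surface_temp, lai, species)
    cut = rs.cuticular_resistance(baselines["rlu"], lai, species)
    low = rs.lower_canopy_resistance(baselines["rcl_so2"], baselines["rcl_o3"],
                                     met.solar_radiation, species)
    grd = rs.ground_resistance(baselines["rac"], baselines["rgs_so2"],
                               baselines["rgs_o3"], species)
    return rs.ResistanceSet(aerodynamic=ra, boundary=rb,
                            stomatal_mesophyll=stom, cuticular=cut,
                            lower_canopy=low, ground=grd)


def point_velocity(met: MetRecord, table: LandCategoryTable, category: str,
                   season: int, lai: float, species: SpeciesParams,
                   z0: float | None = None, zref: float = 10.0) -> float:
    """Deposition velocity (m s-1) for one category at one point/hour."""
    if z0 is None:
        z0 = float(table.z0[category])
    rset = point_resistances(met, table.row(category, season), lai, z0,
                             species, zref)
    return float(rs.deposition_velocity(rset))


def cell_velocity(velocities, fractions):
    """Area-fraction-weighted grid-cell velocity.

    ``fractions`` must be non-negative and sum to 1 within 1e-6 along the
    leading (category) axis.
    """
    v = np.asarray(velocities, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("land-use fractions must be >= 0")
    total = f.sum(axis=0)
    if not np.allclose(total, 1.0, atol=1e-6):
        bad = np.asarray(total).ravel()
        worst = bad[np.argmax(np.abs(bad - 1.0))]
        raise ValueError(
            f"land-use fractions must sum to 1 within 1e-6 (got sum {worst})")
    return np.sum(v * f, axis=0)


def _check_alignment(met: xr.Dataset, surface: xr.Dataset):
    for ax in ("lat", "lon"):
        if not np.array_equal(met[ax].values, surface[ax].values):
            raise ValueError(f"met and surface grids differ on axis {ax!r}")


def lai_at_times(surface: xr.Dataset, times, category: str) -> np.ndarray:
    """Linearly interpolate the weekly LAI series of one category to hourly
    timestamps; shape (time, lat, lon).  Weeks are anchored at mid-week
    day-of-year (3.5 + 7 i) and wrap cyclically at the year boundary."""
    lai = surface["lai"].sel(category=category).values  # (week, lat, lon)
    nweek = lai.shape[0]
    doy = (pd.DatetimeIndex(np.asarray(times)).dayofyear.to_numpy()
           + pd.DatetimeIndex(np.asarray(times)).hour.to_numpy() / 24.0)
    centers = 3.5 + 7.0 * np.arange(nweek)
    period = 7.0 * nweek
    # cyclic linear interpolation on the week axis
    pos = np.interp((doy - 3.5) % period, np.arange(nweek + 1) * 7.0,
                    np.arange(nweek + 1))
    i0 = np.floor(pos).astype(int) % nweek
    i1 = (i0 + 1) % nweek
    w = (pos - np.floor(pos))[:, None, None]
    return (1 - w) * lai[i0] + w * lai[i1]


def velocity_field(met: xr.Dataset, surface: xr.Dataset,
                   species: SpeciesParams,
                   table: LandCategoryTable | None = None,
                   zref: float = 10.0, ocean_velocity: float = 0.0,
                   f0_region=None) -> xr.DataArray:
    """Hourly deposition-velocity map (m s-1) over the grid.

    Parameters
    ----------
    met : xr.Dataset
        Hourly meteorology with dims (time, lat, lon); variables
        ``air_temp``, ``surface_temp``, ``friction_velocity``,
        ``solar_radiation`` and optionally ``stability_param``.
    surface : xr.Dataset
        Land-surface state: ``fraction`` (category, lat, lon), ``lai``
        (week, category, lat, lon) and optionally per-cell ``z0``
        (category, lat, lon).
    species : SpeciesParams
        Gas parameters; ``f0_region`` may override the reactivity for one
        category inside a mask as ``(mask, category, f0)``.
    ocean_velocity : float
        Constant velocity (m s-1) applied to the water category, which is
        outside the resistance scheme's scope.
    """
    table = table or LandCategoryTable.default()
    _check_alignment(met, surface)
    times = met["time"].values
    lat = met["lat"].values
    season = season_of_time(times, lat)  # (time, lat)

    ustar = met["friction_velocity"].values
    srad = met["solar_radiation"].values
    tsurf = met["surface_temp"].values
    zeta = (met["stability_param"].values
            if "stability_param" in met else np.zeros_like(ustar))

    frac = surface["fraction"]
    out = np.zeros(ustar.shape)

    for cat in CATEGORIES:
        f = frac.sel(category=cat).values  # (lat, lon)
        if not np.any(f > 0):
            continue
        if cat == WATER:
            out += f[None, :, :] * ocean_velocity
            continue
        if "z0" in surface:
            z0 = surface["z0"].sel(category=cat).values[None, :, :]
        else:
            z0 = float(table.z0[cat])
        lai = lai_at_times(surface, times, cat)  # (time, lat, lon)
        base = table.rows(cat, season)  # dict of (time, lat) arrays
        b3 = {k: v[:, :, None] for k, v in base.items()}

        ra = rs.aerodynamic_resistance(ustar, z0, zref, zeta)
        rb = rs.boundary_resistance(ustar, species)
        vd = _category_vd(b3, srad, tsurf, lai, ra, rb, species)

        if f0_region is not None and f0_region[1] == cat:
            mask, _, f0 = f0_region
            sp2 = species.with_reactivity(f0)
            rb2 = rs.boundary_resistance(ustar, sp2)
            vd2 = _category_vd(b3, srad, tsurf, lai, ra, rb2, sp2)
            m = np.asarray(mask, dtype=bool)[None, :, :]
            vd = np.where(m, vd2, vd)

        out += f[None, :, :] * vd

    da = xr.DataArray(out, coords={"time": times, "lat": lat,
                                   "lon": met["lon"].values},
                      dims=("time", "lat", "lon"), name="deposition_velocity")
    da.attrs.update(units="m s-1", species=species.name)
    return da


def _category_vd(base, srad, tsurf, lai, ra, rb, species):
    stom = rs.stomatal_mesophyll_resistance(base["ri"], srad, tsurf, lai,
                                            species)
    cut = rs.cuticular_resistance(base["rlu"], lai, species)
    low = rs.lower_canopy_resistance(base["rcl_so2"], base["rcl_o3"], srad,
                                     species)
    grd = rs.ground_resistance(base["rac"], base["rgs_so2"], base["rgs_o3"],
                               species)
    rc = rs.surface_resistance(stom, cut, low, grd)
    total = ra + rb + rc
    with np.errstate(divide="ignore"):
        return np.where(np.isfinite(total), 1.0 / total, 0.0)
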