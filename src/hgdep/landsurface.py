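"""Land-surface state: category fractions, LAI, areas, and transforms.

A surface map is an :class:`xarray.Dataset` on a regular lat-lon grid
(cell-centre registration) with:

* ``fraction(category, lat, lon)`` — per-cell coverage of the 11
  dry-deposition categories, summing to 1;
* ``lai(week, category, lat, lon)`` — weekly leaf-area-index series;
* ``z0(category, lat, lon)`` — roughness length, m;
* ``area(lat, lon)`` — spherical cell area, m2.

Transforms here never break fraction normalisation: the 73→11 category
projection conserves coverage, the site land-type override is idempotent,
and savannization reassigns rainforest coverage to savanna in place.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from hgdep.drydep import CATEGORIES

EARTH_RADIUS = 6.371e6  # m

#: Fallback annual-mean LAI per category, used by the site override when a
#: cell carries no LAI information for the requested category.
DEFAULT_LAI = {
    "deciduous_forest": 4.0, "coniferous_forest": 4.0,
    "tropical_rainforest": 5.5, "agricultural": 2.0,
    "grassland_savanna": 1.5, "shrubland": 1.0, "tundra": 0.5,
    "desert_barren": 0.05, "wetland": 2.0, "urban": 0.5, "water": 0.0,
}

ROUGHNESS_FLOOR = 1.0  # m, forested-site override floor


def cell_area(lat_bounds, lon_bounds) -> float:
    """Spherical quadrilateral area (m2): R^2 dlambda (sin p2 - sin p1)."""
    p1, p2 = np.radians(lat_bounds)
    l1, l2 = np.radians(lon_bounds)
    return EARTH_RADIUS ** 2 * (l2 - l1) * (np.sin(p2) - np.sin(p1))


def grid_areas(lat, lon) -> xr.DataArray:
    """Cell areas (m2) for regular cell-centred lat/lon axes."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.diff(lat).mean() if lat.size > 1 else 180.0
    dlon = np.diff(lon).mean() if lon.size > 1 else 360.0
    south = np.clip(lat - dlat / 2, -90, 90)
    north = np.clip(lat + dlat / 2, -90, 90)
    band = (EARTH_RADIUS ** 2 * np.radians(dlon)
            * (np.sin(np.radians(north)) - np.sin(np.radians(south))))
    area = np.repeat(band[:, None], lon.size, axis=1)
    return xr.DataArray(area, coords={"lat": lat, "lon": lon},
                        dims=("lat", "lon"), name="area",
                        attrs={"units": "m2"})


def load_category_mapping() -> pd.Series:
    """Packaged 73-type → 11-category mapping (synthetic stand-in table)."""
    pkg = resources.files("hgdep.data")
    with (pkg / "landtype73_to_11.synthetic.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("source_type")["category"]


def map_categories(source_fractions, mapping: pd.Series | None = None
                   ) -> np.ndarray:
    """Project coverage fractions over 73 source land types onto the 11
    dry-deposition categories (scatter-add; coverage conserved).

    ``source_fractions`` has the source-type axis first and must be
    normalised; the mapping must be total over the source types present.
    """
    mapping = load_category_mapping() if mapping is None else mapping
    src = np.asarray(source_fractions, dtype=float)
    n_src = src.shape[0]
    missing = [t for t in range(n_src) if t not in mapping.index]
    if missing:
        raise ValueError(f"mapping is not total; missing source types {missing}")
    unknown = set(mapping.values) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"mapping targets unknown categories: {unknown}")
    total = src.sum(axis=0)
    if not np.allclose(total, 1.0, atol=1e-6):
        raise ValueError("source fractions must be normalised (sum to 1)")
    out = np.zeros((len(CATEGORIES),) + src.shape[1:])
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    for t in range(n_src):
        out[cat_index[mapping.loc[t]]] += src[t]
    return out


def site_override(surface: xr.Dataset, lat: float, lon: float,
                  target_category: str) -> xr.Dataset:
    """Force the grid cell containing (lat, lon) to 100% of one category.

    Mirrors the treatment of observation sites when extracting modelled
    velocities: the site's land type covers the whole cell, the cell keeps
    its mean LAI for that category (falling back to a category default if
    the cell has none), and the roughness length is floored at 1 m, a value
    representative of forest canopies.  Idempotent.
    """
    if target_category not in CATEGORIES:
        raise ValueError(f"unknown category {target_category!r}")
    out = surface.copy(deep=True)
    i = int(np.argmin(np.abs(surface["lat"].values - lat)))
    j = int(np.argmin(np.abs(surface["lon"].values - lon)))
    ci = list(CATEGORIES).index(target_category)

    frac = out["fraction"].values
    frac[:, i, j] = 0.0
    frac[ci, i, j] = 1.0

    lai = out["lai"].values  # (week, category, lat, lon)
    if not np.any(lai[:, ci, i, j] > 0):
        warnings.warn(
            f"cell ({lat}, {lon}) has no LAI for {target_category!r}; "
            "using the category-default LAI", stacklevel=2)
        lai[:, ci, i, j] = DEFAULT_LAI[target_category]

    if "z0" in out:
        z0 = out["z0"].values
        z0[ci, i, j] = max(z0[ci, i, j], ROUGHNESS_FLOOR)
    return out


def savannize(surface: xr.Dataset, mask: xr.DataArray,
              reference_mask: xr.DataArray | None = None) -> xr.Dataset:
    """Convert rainforest cover to savanna inside ``mask``.

    Within the masked region, tropical-rainforest coverage is reassigned to
    the grassland/savanna category and the savanna weekly LAI series of the
    converted cells is replaced by the mean series over current savanna
    cells (those with savanna coverage inside ``reference_mask``; the whole
    grid by default).  Cells outside the mask are untouched and fraction
    normalisation is preserved.
    """
    m = np.asarray(mask.values if hasattr(mask, "values") else mask,
                   dtype=bool)
    if m.shape != surface["area"].shape:
        raise ValueError("mask is not aligned with the surface grid")
    out = surface.copy(deep=True)
    ci_rf = list(CATEGORIES).index("tropical_rainforest")
    ci_sv = list(CATEGORIES).index("grassland_savanna")

    sav_frac = surface["fraction"].values[ci_sv]
    ref = sav_frac > 0
    if reference_mask is not None:
        ref &= np.asarray(reference_mask.values
                          if hasattr(reference_mask, "values")
                          else reference_mask, dtype=bool)
    if not np.any(ref):
        raise ValueError("no savanna reference cells available for LAI")

    # mean weekly savanna LAI over reference cells, coverage-weighted
    lai = out["lai"].values
    w = sav_frac[ref]
    ref_series = (lai[:, ci_sv][:, ref] * w).sum(axis=1) / w.sum()

    frac = out["fraction"].values
    converted = m & (frac[ci_rf] > 0)
    frac[ci_sv][converted] += frac[ci_rf][converted]
    frac[ci_rf][converted] = 0.0
    lai[:, ci_sv, converted] = ref_series[:, None]
    lai[:, ci_rf, converted] = 0.0
    return out
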