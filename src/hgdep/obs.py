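"""Deriving Hg0 dry-deposition velocities from site flux measurements.

Forest-site databases report annual litterfall, throughfall and open-field
wet-deposition fluxes (ug m-2 yr-1) alongside atmospheric Hg0
concentrations referenced to STP (273 K, 1 atm).  The dry-deposition
velocity follows from v = F / C after two corrections:

* total foliar uptake = litterfall + throughfall - open-field wet
  deposition, the total dry-deposited Hg to foliage (throughfall washes
  adsorbed Hg off leaf surfaces; the open-field wet flux removes the
  contribution that would have arrived by rain anyway);
* the STP concentration is rescaled to local temperature and pressure by
  ideal-gas number density, C_local = C_stp (273/T)(P/1 atm).

Expected site-database columns (one row per site-method-year):
``site_id, lat, lon, elevation_m, year, land_class, amazon, method,
litterfall_flux, throughfall_flux, openfield_wetdep_flux,
net_exchange_flux, hg0_conc_stp, local_temp, local_pressure``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 365-day year, s (flux/velocity conversions).
SECONDS_PER_YEAR = 3.1536e7

STP_TEMPERATURE = 273.0  # K
METHODS = ("litterfall", "total_foliar", "micromet")


def foliar_uptake(litterfall, throughfall, wetdep):
    """Total foliar uptake flux = litterfall + throughfall - wet deposition.

    All fluxes in ug m-2 yr-1, each >= 0.  A negative result (wet
    deposition exceeding the canopy fluxes) is physically suspect but
    retained, with a warning.
    """
    lf, tf, wd = (np.asarray(x, dtype=float) for x in
                  (litterfall, throughfall, wetdep))
    for name, arr in (("litterfall", lf), ("throughfall", tf),
                      ("wetdep", wd)):
        if np.any(arr < 0):
            raise ValueError(f"{name} flux must be >= 0")
    flux = lf + tf - wd
    if np.any(flux < 0):
        warnings.warn("negative total foliar uptake flux (wet deposition "
                      "exceeds litterfall + throughfall); retained",
                      stacklevel=2)
    return flux[()] if np.ndim(flux) == 0 else flux


def stp_to_local(c_stp, temperature, pressure_atm):
    """Rescale an STP-referenced concentration to local T and P.

    Ideal-gas number density at fixed mixing ratio:
    C_local = C_stp * (273 K / T) * (P / 1 atm).
    """
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure_atm, dtype=float)
    if np.any(t <= 0) or np.any(p <= 0):
        raise ValueError("temperature and pressure must be > 0")
    out = np.asarray(c_stp, dtype=float) * (STP_TEMPERATURE / t) * p
    return out[()] if np.ndim(out) == 0 else out


def velocity_from_flux(flux, c_local):
    """Deposition velocity (cm s-1) from an annual flux and concentration.

    v = F / C with F in ug m-2 yr-1 and C in ng m-3 at local conditions.
    """
    f = np.asarray(flux, dtype=float)
    c = np.asarray(c_local, dtype=float)
    if np.any(f < 0):
        raise ValueError("flux must be >= 0")
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0")
    # ug m-2 yr-1 -> ug m-2 s-1; ng m-3 -> ug m-3; m s-1 -> cm s-1
    out = f / SECONDS_PER_YEAR / (c * 1e-3) * 100.0
    return out[()] if np.ndim(out) == 0 else out


def flux_from_velocity(v_cms, c_local):
    """Inverse of :func:`velocity_from_flux`: F = v C (ug m-2 yr-1)."""
    out = (np.asarray(v_cms, dtype=float) / 100.0
           * np.asarray(c_local, dtype=float) * 1e-3 * SECONDS_PER_YEAR)
    return out[()] if np.ndim(out) == 0 else out


def _method_flux(row: pd.Series) -> float:
    if row["method"] == "litterfall":
        return row["litterfall_flux"]
    if row["method"] == "total_foliar":
        return foliar_uptake(row["litterfall_flux"], row["throughfall_flux"],
                             row["openfield_wetdep_flux"])
    if row["method"] == "micromet":
        return row.get("net_exchange_flux", np.nan)
    raise ValueError(f"unknown method {row['method']!r}")


def derive_velocities(db: pd.DataFrame) -> pd.DataFrame:
    """Annual dry-deposition velocities for every usable database record.

    Records without a positive Hg0 concentration, or with the fluxes their
    method requires missing, are skipped (with a logged reason).  Negative
    total-foliar fluxes are flagged and excluded from the velocity (a
    velocity must be >= 0) but kept in the returned flux column.
    """
    rows = []
    for _, rec in db.iterrows():
        method = rec["method"]
        if method not in METHODS:
            logger.info("site %s: unknown method %r skipped",
                        rec.get("site_id"), method)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flux = _method_flux(rec)
        if pd.isna(flux):
            logger.info("site %s (%s): required flux missing; skipped",
                        rec.get("site_id"), method)
            continue
        c_stp = rec.get("hg0_conc_stp", np.nan)
        if pd.isna(c_stp) or c_stp <= 0:
            logger.info("site %s: no usable Hg0 concentration; skipped",
                        rec.get("site_id"))
            continue
        t = rec.get("local_temp", STP_TEMPERATURE)
        p = rec.get("local_pressure", 1.0)
        c_local = stp_to_local(c_stp, t, p)
        negative = flux < 0
        rows.append({
            "site_id": rec["site_id"],
            "lat": rec.get("lat", np.nan), "lon": rec.get("lon", np.nan),
            "method": method,
            "land_class": rec.get("land_class"),
            "amazon": bool(rec.get("amazon", False)),
            "flux": flux,
            "correction_factor": c_local / c_stp,
            "v_dep": (np.nan if negative
                      else velocity_from_flux(flux, c_local)),
            "negative_flux_flag": negative,
        })
    return pd.DataFrame(rows)


def group_stats(velocities: pd.DataFrame, by=("method",),
                value: str = "v_dep") -> pd.DataFrame:
    """Median, quartiles (linear/type-7 interpolation) and count per group."""
    def _stats(s: pd.Series) -> pd.Series:
        vals = s.dropna().to_numpy()
        if vals.size == 0:
            raise ValueError("group has no usable records")
        return pd.Series({
            "median": np.quantile(vals, 0.5),
            "q1": np.quantile(vals, 0.25),
            "q3": np.quantile(vals, 0.75),
            "n": vals.size,
        })
    out = velocities.groupby(list(by))[value].apply(_stats).unstack()
    out["n"] = out["n"].astype(int)
    return out


def model_obs_compare(model: pd.DataFrame, obs: pd.DataFrame,
                      on: str = "site_id", by=("method",)) -> dict:
    """Per-site and per-group model-observation comparison.

    ``model`` and ``obs`` carry ``v_dep`` (cm s-1) matched on ``on``.
    Returns per-site ratios/differences and per-group medians of the
    observation/model ratio and of both velocities.
    """
    merged = model.merge(obs, on=on, suffixes=("_model", "_obs"))
    if merged.empty:
        raise ValueError(f"no matched records on {on!r}")
    merged["ratio_obs_model"] = merged["v_dep_obs"] / merged["v_dep_model"]
    merged["bias"] = merged["v_dep_model"] - merged["v_dep_obs"]
    group_cols = [c for c in
                  (f"{b}_obs" if f"{b}_obs" in merged else b for b in by)
                  if c in merged]
    stat_cols = ["v_dep_model", "v_dep_obs", "ratio_obs_model", "bias"]
    if group_cols:
        groups = merged.groupby(group_cols)[stat_cols].median()
        groups["n"] = merged.groupby(group_cols).size()
    else:
        groups = merged[stat_cols].median().to_frame("all").T
        groups["n"] = len(merged)
    return {"per_site": merged, "per_group": groups}
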