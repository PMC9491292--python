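"""Resistance-in-series building blocks for gaseous dry deposition.

The deposition velocity of a gas is modelled as the inverse of three
resistances in series,

    v_d = 1 / (Ra + Rb + Rc),

with Ra the aerodynamic resistance (turbulent transfer through the surface
layer), Rb the quasi-laminar boundary-layer resistance, and Rc the bulk
surface (canopy) resistance.  Rc combines four parallel uptake pathways —
stomata+mesophyll, upper-canopy cuticles, lower-canopy surfaces, and the
ground (in-canopy transfer + soil/litter) — each scaled from SO2/O3
reference baselines by the gas's solubility H* and reactivity f0.

All functions are numpy-vectorised; a blocked pathway is represented by the
sentinel ``BLOCKED`` (+inf), never by a division error.  Units are SI
throughout (s m-1, m s-1, K, Pa, W m-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hgdep.species import SpeciesParams

#: Sentinel for a blocked (infinitely resistive) deposition pathway.
BLOCKED = np.inf

#: Von Karman constant.
VON_KARMAN = 0.4

#: Schmidt/Prandtl ratio for water vapour in air (nu = 0.15 cm2 s-1,
#: D_H2O = 0.234 cm2 s-1, Pr = 0.72); multiplied by the species'
#: diffusivity ratio to give its Sc/Pr.
SC_PR_WATER = 0.89

#: Table values at or above this threshold mean "pathway blocked".
_TABLE_BLOCKED = 9999.0


def _asfloat(x):
    return np.asarray(x, dtype=float)


def from_table(r):
    """Map tabulated baseline resistances to floats, 9999 -> BLOCKED."""
    r = _asfloat(r)
    return np.where(r >= _TABLE_BLOCKED, BLOCKED, r)


def parallel_resistance(*resistances):
    """Combine parallel pathway resistances: 1/Rc = sum(1/R_i).

    Blocked (infinite) pathways contribute zero conductance; if every
    pathway is blocked the result is ``BLOCKED``.
    """
    conductance = 0.0
    for r in resistances:
        r = _asfloat(r)
        with np.errstate(divide="ignore", over="ignore"):
            conductance = conductance + np.where(r > 0, 1.0 / r, np.inf)
    with np.errstate(divide="ignore"):
        out = np.where(conductance > 0, 1.0 / conductance, BLOCKED)
    return out[()] if np.ndim(out) == 0 else out


def stability_correction(stability_param):
    """Integrated similarity correction Psi_h for heat/scalars.

    ``stability_param`` is zeta = zref/L (Monin–Obukhov).  Businger–Dyer
    forms: unstable (zeta < 0) gives Psi_h > 0 (faster transfer), stable
    (zeta > 0) gives Psi_h = -5 zeta < 0.  zeta = 0 is the neutral limit.
    """
    zeta = _asfloat(stability_param)
    unstable = zeta < 0
    x2 = np.sqrt(np.where(unstable, 1.0 - 16.0 * zeta, 1.0))
    psi_unstable = 2.0 * np.log((1.0 + x2) / 2.0)
    psi = np.where(unstable, psi_unstable, -5.0 * zeta)
    return psi[()] if np.ndim(psi) == 0 else psi


def aerodynamic_resistance(friction_velocity, z0, zref=10.0, stability_param=0.0):
    """Aerodynamic resistance Ra = [ln(zref/z0) - Psi_h] / (k u*).

    Parameters
    ----------
    friction_velocity : array_like
        Surface friction velocity u*, m s-1; must be > 0.
    z0 : array_like
        Roughness length, m; must be > 0 and < zref.
    zref : float
        Reference height, m (default 10).
    stability_param : array_like
        zeta = zref/L; 0 gives the neutral log-law limit.

    Ra is floored at zero (strongly unstable corrections cannot make the
    turbulent pathway a source).
    """
    ustar = _asfloat(friction_velocity)
    z0 = _asfloat(z0)
    if np.any(ustar <= 0):
        raise ValueError("friction_velocity must be > 0 for aerodynamic_resistance")
    if np.any(z0 <= 0):
        raise ValueError("z0 must be > 0")
    if np.any(z0 > zref):
        raise ValueError("z0 must not exceed zref")
    psi = stability_correction(stability_param)
    ra = (np.log(zref / z0) - psi) / (VON_KARMAN * ustar)
    ra = np.maximum(ra, 0.0)
    return ra[()] if np.ndim(ra) == 0 else ra


def schmidt_prandtl(species: SpeciesParams) -> float:
    """Sc/Pr ratio of the species, from its water-vapour diffusivity ratio."""
    return SC_PR_WATER * species.diffusivity_ratio


def boundary_resistance(friction_velocity, species: SpeciesParams):
    """Quasi-laminar boundary resistance Rb = (2 / k u*) (Sc/Pr)^(2/3).

    u* = 0 means no turbulent transfer at all: the pathway is blocked
    (``BLOCKED`` sentinel) rather than an error.
    """
    ustar = _asfloat(friction_velocity)
    if np.any(ustar < 0):
        raise ValueError("friction_velocity must be >= 0")
    scpr = schmidt_prandtl(species)
    with np.errstate(divide="ignore"):
        rb = np.where(ustar > 0,
                      2.0 / (VON_KARMAN * np.where(ustar > 0, ustar, 1.0))
                      * scpr ** (2.0 / 3.0),
                      BLOCKED)
    return rb[()] if np.ndim(rb) == 0 else rb


def light_response(solar_radiation):
    """Stomatal light-limitation factor 1 + [200/(G + 0.1)]^2 (G in W m-2)."""
    g = _asfloat(solar_radiation)
    return 1.0 + (200.0 / (g + 0.1)) ** 2


def temperature_response(surface_temp):
    """Stomatal temperature factor 400/[Ts(40 - Ts)], Ts in deg C.

    Outside the physiological range (0, 40) C stomata are closed and the
    factor is ``BLOCKED``.
    """
    ts = _asfloat(surface_temp) - 273.15
    open_ = (ts > 0.0) & (ts < 40.0)
    ts_safe = np.where(open_, ts, 20.0)
    fac = np.where(open_, 400.0 / (ts_safe * (40.0 - ts_safe)), BLOCKED)
    return fac[()] if np.ndim(fac) == 0 else fac


def mesophyll_resistance(species: SpeciesParams):
    """Mesophyll resistance Rm = 1 / (H*/3000 + 100 f0), s m-1."""
    denom = species.henry_const / 3000.0 + 100.0 * species.reactivity
    return 1.0 / denom if denom > 0 else BLOCKED


def stomatal_mesophyll_resistance(ri, solar_radiation, surface_temp, lai,
                                  species: SpeciesParams):
    """Combined stomatal + mesophyll pathway resistance Rs + Rm.

    Rs scales the tabulated minimum stomatal resistance ``ri`` by light and
    temperature limitation and the species' diffusivity ratio, and divides
    by LAI (a canopy of leaves acts as parallel stomatal conductors).
    Stomata close at night (G = 0); LAI = 0 blocks the pathway entirely.
    """
    ri = from_table(ri)
    lai = _asfloat(lai)
    if np.any(lai < 0):
        raise ValueError("lai must be >= 0")
    g = _asfloat(solar_radiation)
    rm = mesophyll_resistance(species)
    factor = light_response(g) * temperature_response(surface_temp)
    open_ = (g > 0) & (lai > 0) & np.isfinite(factor) & np.isfinite(ri)
    lai_safe = np.where(lai > 0, lai, 1.0)
    with np.errstate(invalid="ignore", over="ignore"):
        rs = np.where(open_,
                      ri * factor * species.diffusivity_ratio / lai_safe,
                      BLOCKED)
    out = rs + rm
    return out[()] if np.ndim(out) == 0 else out


def cuticular_resistance(rlu_base, lai, species: SpeciesParams):
    """Cuticular pathway Rlu = rlu_base / [(1e-5 H* + f0) * LAI].

    The H*/f0 denominator expresses dissolution and reaction as parallel
    leaf-surface uptake routes; the LAI factor scales the available cuticle
    area (LAI = 0 blocks the pathway).  An inert, insoluble gas
    (H* = f0 = 0) is blocked, not a division error.
    """
    rlu = from_table(rlu_base)
    lai = _asfloat(lai)
    scale = 1e-5 * species.henry_const + species.reactivity
    if scale <= 0:
        shaped = np.broadcast_arrays(rlu, lai)[0]
        out = np.full_like(_asfloat(shaped), BLOCKED)
        return out[()] if np.ndim(out) == 0 else out
    lai_safe = np.where(lai > 0, lai, 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(lai > 0, rlu / (scale * lai_safe), BLOCKED)
    return out[()] if np.ndim(out) == 0 else out


def _scaled_reference(r_so2, r_o3, species: SpeciesParams):
    """Combine SO2/O3 reference baselines: 1/(H*/(1e5 R_S) + f0/R_O)."""
    r_so2 = from_table(r_so2)
    r_o3 = from_table(r_o3)
    with np.errstate(divide="ignore"):
        cond = (species.henry_const / 1e5 * np.where(r_so2 > 0, 1.0 / r_so2, np.inf)
                + species.reactivity * np.where(r_o3 > 0, 1.0 / r_o3, np.inf))
    with np.errstate(divide="ignore"):
        out = np.where(cond > 0, 1.0 / cond, BLOCKED)
    return out


def lower_canopy_resistance(rcl_so2, rcl_o3, solar_radiation,
                            species: SpeciesParams):
    """Lower-canopy pathway Rdc + Rcl.

    Rdc = 100 [1 + 1000/(G + 10)] is the gas-phase transfer resistance to
    exposed lower-canopy surfaces (buoyant convection term); Rcl scales the
    SO2/O3 reference baselines by H* and f0.
    """
    g = _asfloat(solar_radiation)
    rdc = 100.0 * (1.0 + 1000.0 / (g + 10.0))
    out = rdc + _scaled_reference(rcl_so2, rcl_o3, species)
    return out[()] if np.ndim(out) == 0 else out


def ground_resistance(rac, rgs_so2, rgs_o3, species: SpeciesParams):
    """Ground pathway Rac + Rgs: in-canopy aerodynamic + scaled soil/litter."""
    rac = from_table(rac)
    out = rac + _scaled_reference(rgs_so2, rgs_o3, species)
    return out[()] if np.ndim(out) == 0 else out


def surface_resistance(stomatal, cuticular, lower_canopy, ground):
    """Bulk surface resistance from the four parallel pathways."""
    return parallel_resistance(stomatal, cuticular, lower_canopy, ground)


@dataclass
class ResistanceSet:
    """All resistances (s m-1) entering one deposition-velocity evaluation."""

    aerodynamic: float
    boundary: float
    stomatal_mesophyll: float = BLOCKED
    cuticular: float = BLOCKED
    lower_canopy: float = BLOCKED
    ground: float = BLOCKED
    surface: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.surface is None:
            self.surface = surface_resistance(
                self.stomatal_mesophyll, self.cuticular,
                self.lower_canopy, self.ground)


def deposition_velocity(r: ResistanceSet):
    """v_d = 1/(Ra + Rb + Rc) in m s-1; a blocked surface gives v_d = 0."""
    total = _asfloat(r.aerodynamic) + _asfloat(r.boundary) + _asfloat(r.surface)
    with np.errstate(divide="ignore"):
        vd = np.where(np.isfinite(total), 1.0 / total, 0.0)
    return vd[()] if np.ndim(vd) == 0 else vd
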