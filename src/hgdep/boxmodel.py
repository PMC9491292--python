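"""Three-box atmospheric Hg0/Hg2+ mass balance for tuning reduction.

Strengthening the vegetation sink of Hg0 depletes atmospheric Hg0; global
models compensate by increasing the aqueous Hg2+ photoreduction rate,
parametrized as a tuned coefficient alpha times a base rate (the photolysis
and organic-aerosol dependence is folded into the base rate here).  This
module reproduces that tuning loop cheaply: three well-mixed boxes
(Northern-Hemisphere extratropics, tropics, Southern-Hemisphere
extratropics) carry Hg0 and Hg2+ burdens (Mg) coupled by first-order
oxidation, reduction, deposition, prompt re-emission of a fraction of
terrestrial Hg2+ deposition, inter-box exchange, and emissions.  The
system is linear, so the steady state is a direct solve and the response
of surface Hg0 to alpha is monotone — the tuned alpha is unique.

Default rates are illustrative, chosen to give global scales of roughly
3600 Mg Hg0 burden, a ~6-month total-Hg lifetime and 8000 Mg/yr emissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

#: Surface air density used to convert a mean mixing ratio to a surface
#: concentration, kg m-3.
SURFACE_AIR_DENSITY = 1.2

MG_TO_NG = 1e15


@dataclass
class BoxModelConfig:
    """Rates (yr-1), masses (kg), emissions (Mg/yr) and the alpha scale."""

    boxes: tuple = ("nh", "tropics", "sh")
    #: air mass per box, kg (global 5.14e18 split 25/50/25 by area)
    air_mass: tuple = (1.285e18, 2.57e18, 1.285e18)
    k_ox: tuple = (1.8, 2.0, 1.6)          # Hg0 -> Hg2+ oxidation
    k_red: tuple = (10.0, 10.0, 10.0)      # base reduction rate, scaled by alpha
    k_dep_hg0: tuple = (0.8, 0.55, 0.2)    # Hg0 dry deposition (land + ocean)
    k_dep_hg2: tuple = (40.0, 40.0, 40.0)  # Hg2+ wet + dry deposition
    terrestrial_fraction: tuple = (0.4, 0.3, 0.1)  # of Hg2+ deposition to land
    reemission_fraction: float = 0.2       # prompt Hg2+ -> Hg0 re-emission
    #: inter-box exchange (i, j, timescale yr): flux = (x_i - x_j)/tau
    exchange: tuple = (("nh", "tropics", 1.0), ("tropics", "sh", 1.0))
    emissions_hg0: tuple = (4800.0, 2400.0, 800.0)  # Mg/yr
    emissions_hg2: tuple = (0.0, 0.0, 0.0)
    alpha: float = 0.3

    def __post_init__(self):
        n = len(self.boxes)
        for name in ("air_mass", "k_ox", "k_red", "k_dep_hg0", "k_dep_hg2",
                     "terrestrial_fraction", "emissions_hg0", "emissions_hg2"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.shape != (n,):
                raise ValueError(f"{name} must have one value per box")
            if np.any(vals < 0):
                raise ValueError(f"{name} entries must be >= 0")
        if not 0 <= self.reemission_fraction <= 1:
            raise ValueError("reemission_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "BoxModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exchange" in raw:
            raw["exchange"] = tuple(tuple(e) for e in raw["exchange"])
        for key in ("boxes", "air_mass", "k_ox", "k_red", "k_dep_hg0",
                    "k_dep_hg2", "terrestrial_fraction", "emissions_hg0",
                    "emissions_hg2"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def index(self, box: str) -> int:
        return self.boxes.index(box)


@dataclass
class BoxModelState:
    """Per-box Hg0 and Hg2+ burdens, Mg."""

    hg0: np.ndarray
    hg2: np.ndarray

    def vector(self) -> np.ndarray:
        return np.concatenate([self.hg0, self.hg2])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "BoxModelState":
        n = x.size // 2
        return cls(hg0=x[:n].copy(), hg2=x[n:].copy())


def surface_concentration(state: BoxModelState, config: BoxModelConfig
                          ) -> np.ndarray:
    """Per-box surface Hg0 concentration, ng m-3.

    The box burden is taken as well mixed; the mean mixing ratio is
    converted to a surface concentration with the surface air density:
    c = burden * rho / M_air.
    """
    m_air = np.asarray(config.air_mass, dtype=float)
    return state.hg0 * MG_TO_NG * SURFACE_AIR_DENSITY / m_air


def _system_matrix(config: BoxModelConfig):
    """Linear system dx/dt = A x + e over x = (hg0 per box, hg2 per box)."""
    n = len(config.boxes)
    k_ox = np.asarray(config.k_ox, dtype=float)
    k_red = config.alpha * np.asarray(config.k_red, dtype=float)
    kd0 = np.asarray(config.k_dep_hg0, dtype=float)
    kd2 = np.asarray(config.k_dep_hg2, dtype=float)
    reem = config.reemission_fraction * np.asarray(
        config.terrestrial_fraction, dtype=float) * kd2

    a = np.zeros((2 * n, 2 * n))
    for i in range(n):
        a[i, i] -= k_ox[i] + kd0[i]
        a[n + i, i] += k_ox[i]
        a[n + i, n + i] -= k_red[i] + kd2[i]
        a[i, n + i] += k_red[i] + reem[i]
    for bi, bj, tau in config.exchange:
        i, j = config.index(bi), config.index(bj)
        for off in (0, n):
            a[off + i, off + i] -= 1.0 / tau
            a[off + i, off + j] += 1.0 / tau
            a[off + j, off + j] -= 1.0 / tau
            a[off + j, off + i] += 1.0 / tau
    e = np.concatenate([np.asarray(config.emissions_hg0, dtype=float),
                        np.asarray(config.emissions_hg2, dtype=float)])
    return a, e


def tendencies(state: BoxModelState, config: BoxModelConfig) -> BoxModelState:
    """d(burden)/dt (Mg/yr) for every box and species."""
    a, e = _system_matrix(config)
    return BoxModelState.from_vector(a @ state.vector() + e)


def steady_state(config: BoxModelConfig) -> BoxModelState:
    """Direct linear solve of A x = -e; residual checked against fluxes."""
    a, e = _system_matrix(config)
    x = np.linalg.solve(a, -e)
    if np.any(x < -1e-9 * max(x.max(), 1.0)):
        raise ValueError("steady state has negative burdens; check rates")
    resid = np.abs(a @ x + e).max()
    scale = max(np.abs(a @ x).max(), np.abs(e).max(), 1.0)
    if resid > 1e-10 * scale:
        raise RuntimeError(f"steady-state residual {resid:.3e} too large")
    return BoxModelState.from_vector(np.maximum(x, 0.0))


def transient(config: BoxModelConfig, state0: BoxModelState, t_years: float,
              **ivp_kwargs) -> BoxModelState:
    """Adaptive explicit integration, for diagnostics/cross-checks only."""
    a, e = _system_matrix(config)
    sol = solve_ivp(lambda t, x: a @ x + e, (0.0, t_years), state0.vector(),
                    rtol=1e-10, atol=1e-8, dense_output=False, **ivp_kwargs)
    return BoxModelState.from_vector(sol.y[:, -1])


def nh_surface_hg0(config: BoxModelConfig) -> float:
    """Steady-state NH-box surface Hg0 concentration, ng m-3."""
    st = steady_state(config)
    return float(surface_concentration(st, config)[config.index("nh")])


def tune_alpha(config: BoxModelConfig, target_nh: float,
               tol: float = 1e-9) -> float:
    """Find the alpha whose steady state matches a target NH Hg0 (ng m-3).

    The NH concentration rises monotonically with alpha (more reduction
    keeps Hg as long-lived Hg0), so the root is unique within the search
    bracket [1e-3 alpha0, 1e3 alpha0].
    """
    import dataclasses

    alpha0 = config.alpha
    lo, hi = 1e-3 * alpha0, 1e3 * alpha0

    def f(alpha):
        return nh_surface_hg0(dataclasses.replace(config, alpha=alpha)) \
            - target_nh

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        feas = sorted((target_nh + flo, target_nh + fhi))
        raise ValueError(
            f"target {target_nh} ng m-3 not bracketed by alpha in "
            f"[{lo:.3g}, {hi:.3g}]; feasible range is "
            f"[{feas[0]:.4g}, {feas[1]:.4g}] ng m-3")
    return brentq(f, lo, hi, xtol=tol * alpha0, rtol=1e-12)


def budget_report(state: BoxModelState, config: BoxModelConfig
                  ) -> pd.DataFrame:
    """Process fluxes (Mg/yr) per box; at steady state, per-species inflows
    balance outflows to solver tolerance."""
    n = len(config.boxes)
    k_red = config.alpha * np.asarray(config.k_red, dtype=float)
    kd2 = np.asarray(config.k_dep_hg2, dtype=float)
    reem = (config.reemission_fraction
            * np.asarray(config.terrestrial_fraction, dtype=float) * kd2)
    rows = []
    ex0 = np.zeros(n)
    ex2 = np.zeros(n)
    for bi, bj, tau in config.exchange:
        i, j = config.index(bi), config.index(bj)
        ex0[i] += (state.hg0[j] - state.hg0[i]) / tau
        ex0[j] += (state.hg0[i] - state.hg0[j]) / tau
        ex2[i] += (state.hg2[j] - state.hg2[i]) / tau
        ex2[j] += (state.hg2[i] - state.hg2[j]) / tau
    for i, box in enumerate(config.boxes):
        rows.append({
            "box": box,
            "emissions_hg0": config.emissions_hg0[i],
            "emissions_hg2": config.emissions_hg2[i],
            "oxidation": config.k_ox[i] * state.hg0[i],
            "reduction": k_red[i] * state.hg2[i],
            "hg0_dry_deposition": config.k_dep_hg0[i] * state.hg0[i],
            "hg2_deposition": kd2[i] * state.hg2[i],
            "prompt_reemission": reem[i] * state.hg2[i],
            "net_exchange_hg0": ex0[i],
            "net_exchange_hg2": ex2[i],
        })
    return pd.DataFrame(rows).set_index("box")
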