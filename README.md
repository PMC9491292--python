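# hgdep

Tools for modelling the uptake of atmospheric elemental mercury (Hg⁰) by
vegetation — the dominant pathway delivering atmospheric Hg to terrestrial
ecosystems — and for confronting that model with field measurements.

The package is aimed at atmospheric-chemistry and biogeochemistry
researchers who want to work with the dry-deposition machinery of a global
mercury model *offline*: no chemistry-transport simulation, just the
deposition physics, the observational derivations, and the budget
bookkeeping, all runnable on synthetic inputs.

## What it computes

**Dry-deposition velocity.** The flux of a gas to a surface per unit air
concentration, modelled as resistances in series,

    v_d = 1 / (Ra + Rb + Rc),

with aerodynamic (Ra), quasi-laminar boundary (Rb) and bulk surface (Rc)
resistances. Rc combines four parallel canopy pathways — stomata+mesophyll,
cuticles, lower canopy, ground — whose baseline (SO₂/O₃-referenced)
resistances per land category and season are scaled by the gas's effective
Henry's law constant H\* and biological reactivity f₀:

    Rm  = 1 / (H*/3000 + 100 f₀)
    Rlu = Rlu_base / (10⁻⁵ H* + f₀)          (per unit LAI)
    Rgs, Rcl = 1 / (H*/(10⁵ R_SO2) + f₀/R_O3)

For Hg⁰, H\* = 0.11 M atm⁻¹ and f₀ spans 10⁻⁵ (historic reference) to 0.2
(matching Amazon total-foliar-uptake data); gaseous Hg²⁺ has f₀ = 0,
H\* = 10¹⁴ M atm⁻¹. Grid cells mix up to 11 land categories with
area-fraction weighting; over water the scheme defers to an externally
supplied air–sea exchange velocity (default 0).

**Observation-derived velocities.** From site databases of litterfall,
throughfall and open-field wet-deposition fluxes (µg m⁻² yr⁻¹):
total foliar uptake = litterfall + throughfall − wet deposition, and
v = F / C after rescaling STP-referenced Hg⁰ concentrations to local
temperature and pressure. Group medians/IQRs and model-vs-observation bias
tables included.

**Box-model tuning.** A three-box (NH/tropics/SH) linear Hg⁰/Hg²⁺ mass
balance used to tune the aqueous Hg²⁺ photoreduction coefficient α so a
target NH surface Hg⁰ concentration is matched — the cheap stand-in for
re-tuning a full transport model after strengthening the vegetation sink.

**Scenarios.** Land-cover-change experiments (notably Amazon-style
*savannization*: rainforest → savanna with savanna reference LAI), with
regional deposition budgets in Mg yr⁻¹ and an optional box-model step that
re-equilibrates the global balance to the weakened land sink.

**Synthetic data.** Deterministic generators for hourly meteorology with
realistic diurnal/seasonal structure, mixed/coastal land-use grids with a
rainforest block and savanna reference region, and site flux databases with
multiplicative lognormal noise around a known true velocity — so every
stage is testable without downloads.

## Worked example

```sh
$ hgdep synth all --out inputs --seed 5 --nlat 6 --nlon 6 --hours 48
$ hgdep depvel run --met inputs/met.nc --surface inputs/surface.nc \
      --species hg0 --f0 3e-5 --f0-amazon 0.2 --annual-mean --out vd.nc
wrote vd.nc (mean 0.1553 cm s-1)
```

and the core arithmetic from Python:

```python
>>> from hgdep import obs
>>> flux = obs.foliar_uptake(49, 72, 18)   # ug m-2 yr-1
>>> flux
103.0
>>> round(obs.velocity_from_flux(flux, 0.93), 2)   # cm s-1 at 0.93 ng m-3
0.35
```

A total foliar uptake of 103 µg m⁻² yr⁻¹ over an air concentration of
0.93 ng m⁻³ corresponds to an annual deposition velocity of 0.35 cm s⁻¹ —
the kind of upper-bound rainforest value that motivates raising f₀ for the
Amazon. Tuning the box model to a 1.7 ng m⁻³ NH target:

```sh
$ hgdep boxmodel tune --target-nh 1.7
{
  "alpha": 0.4717...,
  "alpha_prior": 0.3,
  "target_nh_ngm3": 1.7,
  "hg0_burden_mg": 3758.1...,
  "hg2_burden_mg": 153.1...
}
```

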