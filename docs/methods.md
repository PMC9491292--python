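# Methods

## The deposition model

The dry-deposition velocity of a gas is the inverse of three resistances in
series, v_d = 1/(Ra + Rb + Rc), the standard big-leaf construction used by
global chemistry models.

**Aerodynamic resistance.** Ra = [ln(z_ref/z₀) − Ψ_h(ζ)]/(k u\*) with
k = 0.4, a 10 m reference height, and the Businger–Dyer similarity
correction Ψ_h (unstable: 2 ln[(1+x²)/2] with x = (1−16ζ)^¼; stable: −5ζ).
When stability information is absent the neutral limit (Ψ_h = 0) is used —
the meteorological generator emits ζ = 0, so default runs are neutral. Ra
is floored at zero.

**Boundary resistance.** Rb = (2/(k u\*))(Sc/Pr)^⅔. The species' Schmidt
number enters through its diffusivity ratio relative to water vapour
(Sc/Pr = 0.89 × D_H₂O/D_x; 1.9 for Hg⁰). Calm air (u\* = 0) blocks the
pathway entirely rather than raising an error.

**Surface resistance.** Four parallel pathways, each read from a seasonal
baseline table per land category and scaled by the gas's effective Henry's
law constant H\* (M atm⁻¹) and biological reactivity f₀ ∈ [0, 1]:

* stomata: Rs = r_i · [1 + (200/(G+0.1))²] · [400/(T_s(40−T_s))] ·
  (D_H₂O/D_x) / LAI, blocked at night (G = 0), outside 0–40 °C, or at
  LAI = 0; plus a mesophyll term Rm = 1/(H\*/3000 + 100 f₀);
* cuticles: Rlu = Rlu_base / [(10⁻⁵ H\* + f₀) · LAI];
* lower canopy: Rdc + Rcl with Rdc = 100[1 + 1000/(G+10)] and
  Rcl = 1/(H\*/(10⁵ R_SO₂) + f₀/R_O₃);
* ground: Rac + Rgs with the same SO₂/O₃ reference combination.

Blocked pathways are a single +inf sentinel; the parallel combination
1/Rc = Σ 1/R_i treats them as zero conductance, so an inert, insoluble gas
(H\* = f₀ = 0) simply does not deposit — no division errors anywhere. All
internal units are SI (s m⁻¹, m s⁻¹, K, Pa); cm s⁻¹ appears only at I/O
boundaries.

The baseline resistance table follows the classic Wesely big-leaf
tabulation (11 categories × 5 seasonal classes, SO₂/O₃ reference values),
shipped as an editable CSV so corrections are one-file edits. The category
set is the one global Hg models use (deciduous, coniferous and tropical
rain forest, agricultural, grassland/savanna, shrubland, tundra, desert,
wetland, urban, water); rainforest carries lush-season values year-round.
Seasonal class is a fixed month/hemisphere lookup (tropics always lush),
overridable per run. Two modelling choices are deliberately isolated in
single functions because their reference formulations vary between hosts:
the LAI scaling (stomatal and cuticular resistances divided by LAI, a
canopy of parallel leaves) and the seasonal lookup.

**Scope limits.** Dry, snow-free surfaces only — wet-canopy and snow
modifications are not implemented. Over water the resistance scheme is not
used at all: ocean Hg⁰ uptake belongs to an air–sea exchange model, so
water cells carry an externally supplied constant velocity (default 0).
Aerosol-phase deposition, oxidation chemistry and transport are out of
scope.

## Grid cells and land surface

Surface maps are regular lat-lon grids (cell centres, default chosen by the
generator; spherical areas by R²Δλ(sin φ₂ − sin φ₁)) with per-cell category
fractions, weekly LAI series (linearly interpolated to hourly, cyclic over
the year) and per-category roughness lengths. Source land-cover data at
73-type granularity is projected to the 11 categories by a total mapping
table (a synthetic stand-in CSV ships with the package; the real Olson
mapping can be dropped in).

For comparing with point observations, the site's cell is overridden to
100% of the observed category, keeping the cell's mean LAI for that
category (category-default LAI if the cell has none) and flooring z₀ at
1 m — representative of forest canopies, and important in coastal cells
where sub-grid water otherwise drags the cell velocity down. The
savannization transform reassigns rainforest coverage to savanna within a
mask and substitutes the coverage-weighted mean weekly LAI of current
savanna reference cells.

## Observation pipeline

Velocities are derived per record as v = F/C. F is the litterfall flux, the
total foliar uptake (litterfall + throughfall − open-field wet deposition),
or a measured net ecosystem exchange flux, in µg m⁻² yr⁻¹; C is the Hg⁰
concentration rescaled from STP (273 K, 1 atm) to local conditions by
ideal-gas number density. Conversions use a 365-day year (3.1536·10⁷ s).
Quartiles use linear (type-7) interpolation. Records lacking a usable
concentration are excluded from velocity statistics but kept for flux
statistics; negative total-foliar fluxes are flagged and retained rather
than dropped, for transparency.

## Box model

Three well-mixed boxes (NH extratropics, tropics, SH extratropics; air
masses 25/50/25% of 5.14·10¹⁸ kg) each carry Hg⁰ and Hg²⁺ burdens (Mg)
with first-order oxidation, reduction (α · k_red — the photolysis-rate and
organic-aerosol dependence of the aqueous photoreduction is folded into the
base rate, leaving α as the tuned scale), Hg⁰ dry deposition, Hg²⁺
wet+dry deposition with 20% of its terrestrial share promptly re-emitted as
Hg⁰, burden-difference inter-box exchange, and emissions. Surface
concentrations convert the well-mixed burden with surface air density
(1.2 kg m⁻³).

The system is linear: the steady state is a direct solve (residual checked
at 10⁻¹⁰ of the flux scale) and transient integration exists only for
cross-checks. Because more reduction monotonically raises Hg⁰, the α that
matches a target NH surface concentration is unique; it is found by Brent's
method over [10⁻³ α₀, 10³ α₀], with an explicit error naming the feasible
concentration range when the target cannot be bracketed.

Default rates are *illustrative*, chosen so the defaults reproduce the
global scales a mercury modeller expects — ≈3650 Mg Hg⁰ burden, ≈6-month
total-Hg lifetime against 8000 Mg yr⁻¹ emissions, NH surface Hg⁰ ≈1.7
ng m⁻³ — not any particular model's calibration. Everything is config
(YAML-loadable), not code.

## Budgets and scenarios

Deposition flux maps are F = v·C (µg m⁻² yr⁻¹); regional budgets are
Σ F·area in Mg yr⁻¹ (unit conversions exact). Scenario deltas run the
velocity model for base and scenario surfaces under identical meteorology
and report land/region budget changes at a fixed concentration field —
they are bookkeeping, not transport, and cannot reproduce the budget
magnitudes a chemistry-transport simulation yields (those require
global meteorology and chemistry and are documented validation context
only). Optionally the relative land-sink change rescales one box's Hg⁰
deposition rate and the box model re-equilibrates: total deposition still
balances emissions, so the weakened regional sink's shortfall appears as
added deposition to the remaining (ocean and other-region) sinks, and the
global burden rises.

## Synthetic data

The generators define the package's study conditions:

* **Meteorology**: hourly fields on the chosen grid; temperature =
  latitude-dependent base + seasonal cycle (amplitude 10 K extratropics,
  hemisphere-phased) + diurnal cycle (5 K, solar-time-phased) + 1 K noise;
  shortwave radiation from true solar geometry (zero at local night,
  polar day/night included) damped by cloud fraction (beta-distributed);
  friction velocity lognormal around 0.35 m s⁻¹; neutral stability.
* **Surface**: an ocean strip, mixed coastal cells, an Amazon-like
  rainforest block (with mask), a savanna reference block, temperate
  mosaics, and a guarantee that all 11 categories occur; Dirichlet-mixed
  fractions; sinusoidal weekly LAI per category with hemisphere phasing.
* **Site database**: n = 50 sites by default; each site's true total
  foliar uptake is v_true·C_local·year times lognormal noise with σ = 0.3
  (fluxes are positive and right-skewed; σ chosen to resemble the spread
  of published site compilations — a modelling choice, not a measured
  value). Litterfall carries 73% of the total (litterfall misses woody
  tissue and wash-off uptake; 0.73 reproduces the ≈36% total-vs-litterfall
  median shift seen in compilations), and throughfall closes the balance
  against a 15% open-field wet-deposition share. Every site yields one
  litterfall and one total-foliar record.

All generators use numpy's PCG64 (`default_rng`) with a mandatory seed;
the fixed regression fixture uses seed 20150101. What the generators do
*not* emulate: spatial covariance of real meteorology, geography, regional
concentration patterns, inter-method site selection biases. Passing tests
therefore demonstrate the correctness of the machinery and its statistical
behaviour under known truth — not agreement with real-world fluxes.

## Problem sizes and numerical choices

Tests and the acceptance script run on an 8×8 grid with two weeks of hourly
meteorology and 50 sites — the package's desk-scale defaults; a full year
over a single cell is used where annual means matter. Tolerances: exact
closed forms at 10⁻¹² relative; linear-solver residuals at 10⁻¹⁰; α
recovery at 10⁻⁶ relative; statistical recoveries at 10% with fixed seeds.
Fraction vectors must sum to 1 within 10⁻⁶; violations are rejected with
the offending sum rather than renormalised silently.

## Known limitations

* The baseline resistance constants are the classic published big-leaf
  values adapted to the 11-category set, not byte-identical to any
  specific model's internal table.
* The LAI dependence of the stomatal/cuticular pathways is the simple
  parallel-leaf division, isolated in one function for easy replacement.
* The box model's topology and rates are schematic; tuned α values are
  meaningful relative to their own configuration, not comparable across
  configurations (or to any transport model's calibrated values).
* No bidirectional exchange: deposited Hg⁰ never re-emits from foliage, so
  modelled fluxes are net-uptake analogues.
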