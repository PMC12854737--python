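# Methods

`icedust` implements the computation chain from airborne and snow
mineral-dust observations on a melting ice-sheet surface to phosphorus
delivery rates and the glacier-ice-algal bloom potential those deliveries
can sustain. This note records the models, their assumptions, the
parameter choices, and what the synthetic-data generators do and do not
emulate.

## Particle sizes

Particle size from 2-D image analysis is the equivalent circular
diameter, d = 2·√(A/π), of the projected area A. Descriptive statistics
are computed after discarding particles above an upper cutoff (default
17 µm, the upper end of the optical particle counter range, so microscopy
and OPC statistics are comparable). Choices the data sources leave open,
fixed here:

* sub-threshold fractions use a strict `<` comparison;
* the standard deviation uses the sample (n−1) denominator;
* histogram bins are half-open `[lo, hi)`, with out-of-range particles
  excluded rather than folded into the end bins, so binning conserves
  particle number exactly.

## Dry-deposition model

Deposition velocity for a particle of diameter d over a uniform melting
snow/ice surface in a neutrally stratified surface layer:

    v_d = v_g + 1 / (r_a + r_b)

* **Settling**: v_g = Cc·ρ_p·d²·g / (18 µ), with the Cunningham slip
  correction Cc = 1 + (2λ/d)(1.257 + 0.4·e^(−1.1 d/2λ)). The mean free
  path λ is corrected from its 0.0665 µm reference value (101.325 kPa,
  288 K) to ambient pressure and temperature with the Sutherland form.
* **Aerodynamic resistance**: r_a = ln(z/z0)/(κ u*), with
  u* = κU/ln(z/z0) from the neutral logarithmic wind profile.
* **Quasi-laminar resistance**: r_b = 1/[u*(Sc^(−2/3) + 10^(−3/St))],
  with Schmidt number Sc = ν/D_B, Brownian diffusivity
  D_B = k_B·T·Cc/(3π µ d), Stokes number St = v_g·u*²/(g ν), and
  kinematic viscosity ν = µ/ρ_air from the ideal-gas air density.

In calm air u* = 0, both resistances diverge and v_d reduces to v_g; the
model guarantees v_d ≥ v_g everywhere. The v_d(d) curve shows the
canonical accumulation-mode minimum at intermediate sizes. This
resistance-in-series formulation is a conventional, fully reproducible
smooth-surface equilibrium parameterization; published campaign flux
values obtained with other members of this model family should be
expected to agree in order of magnitude, not digit-for-digit. Stability
corrections (Monin–Obukhov), rain scavenging and resuspension are out of
scope.

Defaults, all configurable through `DepositionParams`:

| parameter | default | rationale |
|---|---|---|
| ρ_p | 2650 kg·m⁻³ | quartz/feldspar-dominated silicate dust |
| z0 | 1e-4 m | melting snow/ice; v_d for coarse grains is settling-dominated, so the flux is only weakly sensitive to z0 (an order of magnitude in z0 moves r_a by ~25 %) |
| µ_air | 1.716e-5 Pa·s | dry air near 0 °C |
| T, P fallback | 273.15 K, 892 hPa | campaign-mean surface conditions at ~1000 m elevation on the ice sheet |
| κ | 0.4 | standard |

**Flux assembly.** OPC counts per minute per bin are converted to number
concentration with the instrument flow (default 0.22 L·min⁻¹), to mass
with spherical volume at the bin's representative diameter — the
geometric mean of the edges, matching log-spaced OPC bins (default 16
bins over 0.38–17 µm) — and multiplied by v_d evaluated with the met
record joined by nearest timestamp within 1 minute (unmatched steps are
dropped). The campaign mean is expressed in mg·m⁻²·day⁻¹ and annualized
by ×365 exactly.

**Wet and melt-out fluxes** are unit-carrying products: snow particulate
load (mg·kg⁻¹) × snowfall (kg·m⁻²·yr⁻¹), and ice core load (mg·kg⁻¹) ×
ablation (m water equivalent·yr⁻¹) × 1000 kg·m⁻²·mWE⁻¹.

## Phosphorus budget and biomass upscaling

Three pathways: dissolved P in snowfall (concentration × snowfall, 1 kg
water = 1 L), and mineral-bound P in snow-delivered and dry-deposited
dust (dust rate × apatite weight fraction × stoichiometric P fraction of
hydroxylapatite Ca₅(PO₄)₃OH, 3 M_P/M_mineral ≈ 0.185 from IUPAC atomic
masses). The dry-deposited dust is assumed to share the snow dust's
mineralogy (0.3 wt % hydroxylapatite by default). The total is the sum of
the pathway P rates before any quota conversion.

Delivered P converts to algal standing stock with fixed cellular quotas
(P 0.14, C 106, N 4.5 pg·cell⁻¹): cells·m⁻²·yr⁻¹ = P/q_P, diluted into
the meltwater of one season's ablation (default 1 mWE = 10⁶ mL·m⁻²) for
cells·mL⁻¹, and multiplied by q_C, q_N for biomass accumulation in
kg·km⁻²·yr⁻¹. All conversions run internally in picograms/cells/m²/year,
the lossless basis at these magnitudes. Phosphorus-use efficiency is an
explicit parameter with default 1 — an upper bound, not an estimate; the
elution scenario removes a configurable fraction (default 80 %) of the
dissolved pathway before uptake.

**Reporting convention.** The budget object carries two tables. The
exact table propagates unrounded P rates. The "printed" table first
rounds each pathway's P rate to 0.1 mg·m⁻²·yr⁻¹ and derives the
cell/C/N rows from the rounded rates — the convention used in published
summary tables of this kind, and the only way a reader can reproduce such
a table from its own printed P row (e.g. 0.5 → 3.6×10³ cells·mL⁻¹,
whereas the unrounded 0.488 gives 3.5×10³). Total-pathway cell density is
computed from total P, not by summing rounded per-pathway densities.

## REE geochemistry and community summaries

REE patterns are normalized element-wise against a reference
composition; the package ships CI chondrite (McDonough & Sun 1995) and
upper continental crust (Rudnick & Gao 2003) values and accepts any
user-supplied reference — no shipped reference is claimed to match any
particular published figure. The europium anomaly uses the standard
geometric-mean interpolation Eu/Eu* = Eu_N/√(Sm_N·Gd_N) (arithmetic
variant behind a flag); it is scale-invariant by construction.

Taxon count tables (samples × taxa) are converted to per-sample
proportions; a zero-read sample is an error naming the sample. Minor-taxon
lumping keeps the n most abundant taxa by mean relative abundance across
samples (ties broken lexicographically) and assigns the per-sample
residual to an "Other" category, conserving each sample's total exactly.
No rarefaction or denoising is applied — the input boundary is a finished
taxon table.

## Synthetic data: what it emulates

The generators reproduce the statistical structure of a two-campaign
melt-season data set from the southwest Greenland Ice Sheet ablation
zone, so that every stage runs and is testable offline:

* **Diameters** are lognormal, truncated at 17 µm by rejection. The
  lognormal family is an assumption (standard for mineral aerosol), not a
  claim about any observed data set; observed mean ± sd pairs are mapped
  to (meanlog, sdlog) by exact moment matching
  (`lognormal_params_from_moments`). Defaults target 0.76 ± 0.87 µm, the
  dry-filter statistic the pipeline emulates.
* **OPC counts** are per-minute Poisson draws around bin-expected rates
  proportional to the lognormal mass in each bin; the overall rate is set
  by a target mean airborne mass loading (default 0.5 µg·m⁻³, a sub-µg·m⁻³
  dusty-background value) through the mean spherical particle mass over
  the binned range.
* **Meteorology** is a 1-minute series with two regimes: katabatic days
  (south-easterly direction around 142°, Gaussian speeds around
  4.7 m·s⁻¹ truncated at zero) and storm days (westerly, slower winds and
  a pronounced pressure low). Pressure is built from daily anchors
  (clipped to ±2.5 sd around 892 hPa on calm days) interpolated to
  minutes — real surface pressure is smooth on sub-daily scales, and this
  construction guarantees calm-period pressure never dips 3 sd below the
  mean. Because speeds are truncated at zero, the generated mean exceeds
  the nominal mean by ~0.04 m·s⁻¹; recovery checks compare against the
  analytic truncated-normal mean (`truncated_normal_mean`).
* **Snow chemistry** draws particulate loads and dissolved P from
  zero-truncated Gaussians (fresh snow 2.9 ± 1.0 mg·kg⁻¹ and
  1.34 ± 0.3 µg·L⁻¹; weathered snow 12.8 ± 4.5 mg·kg⁻¹ and
  2.29 ± 0.5 µg·L⁻¹). The fresh-snow spreads are not published (n = 2
  means only); the defaults use roughly the weathered-snow coefficient of
  variation (~35 %).
* **Taxon tables** are multinomial draws over a ten-category profile
  shaped like a Proteobacteria/Bacteroidota-dominated bacterial
  community.

One global seed drives everything; each generator uses a deterministic
substream (`SeedSequence([seed, key])`), so outputs are bit-identical for
a fixed seed and independent across generators.

What the generators do **not** emulate: temporal autocorrelation of dust
loading (counts are independent Poisson minutes), wind-direction-dependent
dust sources, particle mixing state or density variation, compositional
covariance between taxa, and measurement error in any instrument. Tests
passing on synthetic data therefore validate the computation chain and
its statistical contracts, not the field estimates themselves.

## Problem sizes and numerical choices

Tests run synthetic campaigns of 1–7 days at 1-minute cadence (1 440 to
10 080 steps, 16 size bins) and particle sets of 10⁴–5×10⁴ — large
enough for the 2–5 % moment-recovery tolerances while keeping the whole
suite in a few seconds. Statistical tests use fixed seeds and 3–4
standard-error bands. Degenerate inputs are handled explicitly: zero
campaign duration yields an empty (not erroneous) count series, sdlog = 0
gives a point mass, a single-observation chemistry group reports its sd
as undefined (NaN), an all-zero budget input yields an all-zero table,
and an empty particle set after the size cutoff raises a dedicated error.

## Known limitations

* The deposition model is one declared member of the resistance-model
  family; no claim is made that it matches any specific SI-only variant
  used elsewhere. At 10 µm and campaign-mean wind the turbulent term
  still contributes ~30 % of v_d; settling dominates fully only beyond
  ~30 µm (the v_d/v_g ≤ 1.05 continuum check applies at ≥100 µm).
* Annualizing a few weeks of campaign flux by ×365 inherits the seasonal
  representativeness caveat of any short-campaign extrapolation.
* The cell-density and biomass numbers are upper bounds conditional on
  100 % P use and fixed quotas; no albedo mapping is provided.
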