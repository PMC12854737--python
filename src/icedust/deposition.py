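"""Size-resolved dry-deposition velocity and dust flux estimation.

The dry-deposition model treats transfer of mineral dust to a melting
snow/ice surface as gravitational settling in parallel with two transport
resistances in series, assuming a uniform surface in equilibrium and a
neutrally stratified surface layer:

    v_d = v_g + 1 / (r_a + r_b)

where

* ``v_g`` is the Stokes settling velocity with the Cunningham slip
  correction,
* ``r_a = ln(z/z0) / (kappa * u*)`` is the aerodynamic resistance from the
  neutral logarithmic wind profile, and
* ``r_b = 1 / [u* (Sc^(-2/3) + 10^(-3/St))]`` is the quasi-laminar
  sublayer resistance combining Brownian diffusion (Schmidt number term)
  and inertial impaction (Stokes number term).

Fluxes follow from optical particle counter (OPC) number counts converted
to per-bin mass concentrations (spherical particles, constant mineral
density) multiplied by the per-bin deposition velocity evaluated with the
concurrent meteorology.  Wet-deposition (snowfall) and ice melt-out
particulate fluxes are simple products of measured loads with snowfall or
ablation rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepositionParams",
    "OPCCampaign",
    "MetSeries",
    "FluxResult",
    "default_bin_edges",
    "slip_correction",
    "settling_velocity",
    "friction_velocity",
    "deposition_velocity",
    "number_concentration",
    "bin_mass_concentration",
    "dry_flux",
    "wet_deposition_rate",
    "meltout_rate",
]

R_SPECIFIC_AIR = 287.05  # J kg-1 K-1, dry air
SUTHERLAND_S = 110.4     # K

#: Campaign-mean surface conditions used when no met series supplies T, P.
DEFAULT_TEMPERATURE_K = 273.15   # 0 degC
DEFAULT_PRESSURE_HPA = 892.0


@dataclass(frozen=True)
class DepositionParams:
    """Physical constants and surface parameters of the deposition model.

    ``mean_free_path_ref`` is the air mean free path (µm) at the reference
    state (101.325 kPa, 288 K); it is pressure/temperature-corrected at use.
    ``roughness_length`` defaults to 1e-4 m, appropriate for melting
    snow/ice; ``particle_density`` defaults to 2650 kg m-3 for
    quartz/feldspar-dominated silicate dust.
    """

    particle_density: float = 2650.0        # kg m-3
    air_viscosity: float = 1.716e-5         # Pa s (near 0 degC)
    mean_free_path_ref: float = 0.0665      # um at 101.325 kPa / 288 K
    von_karman: float = 0.4
    roughness_length: float = 1e-4          # m
    gravity: float = 9.81                   # m s-2
    boltzmann: float = 1.380649e-23         # J K-1

    def __post_init__(self):
        for name in ("particle_density", "air_viscosity", "mean_free_path_ref",
                     "von_karman", "roughness_length", "gravity", "boltzmann"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def mean_free_path(self, temperature_k: float = DEFAULT_TEMPERATURE_K,
                       pressure_hpa: float = DEFAULT_PRESSURE_HPA) -> float:
        """Mean free path (µm) corrected to ambient T (K) and P (hPa)."""
        t_ref, p_ref = 288.0, 1013.25
        return (self.mean_free_path_ref
                * (p_ref / pressure_hpa)
                * (temperature_k / t_ref)
                * (1.0 + SUTHERLAND_S / t_ref)
                / (1.0 + SUTHERLAND_S / temperature_k))

    def with_overrides(self, **kw) -> "DepositionParams":
        return replace(self, **kw)


def default_bin_edges(n_bins: int = 16, lo: float = 0.38, hi: float = 17.0) -> np.ndarray:
    """Log-spaced OPC bin edges (µm), OPC-N2-like 0.38–17 µm by default."""
    return np.geomspace(lo, hi, n_bins + 1)


@dataclass
class OPCCampaign:
    """Time-stamped per-bin particle counts from an optical particle counter."""

    timestamps: pd.DatetimeIndex
    bin_edges: np.ndarray          # um, len = n_bins + 1
    counts: np.ndarray             # (n_times, n_bins) integer counts
    sample_flow: float = 0.22      # L min-1
    interval_min: float = 1.0

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.size < 2 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
        if self.counts.ndim != 2 or self.counts.shape[1] != self.bin_edges.size - 1:
            raise ValueError("counts must be (n_times, n_bins) with n_bins = len(edges)-1")
        if self.counts.shape[0] != self.timestamps.size:
            raise ValueError("counts rows must match timestamps")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.sample_flow <= 0:
            raise ValueError("sample_flow must be positive")

    @property
    def bin_midpoints(self) -> np.ndarray:
        """Representative diameter per bin: geometric mean of the edges."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


@dataclass
class MetSeries:
    """Surface-layer meteorology forcing the deposition-velocity model."""

    timestamps: pd.DatetimeIndex
    wind_speed: np.ndarray             # m s-1
    measurement_height: float = 2.0    # m
    air_temperature: np.ndarray | float = DEFAULT_TEMPERATURE_K   # K
    pressure: np.ndarray | float = DEFAULT_PRESSURE_HPA           # hPa
    wind_direction: np.ndarray | None = None                      # deg

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        n = self.timestamps.size
        self.wind_speed = np.broadcast_to(
            np.asarray(self.wind_speed, dtype=float), (n,)).copy()
        if np.any(self.wind_speed < 0):
            raise ValueError("wind speed must be non-negative")
        if self.measurement_height <= 0:
            raise ValueError("measurement height must be positive")
        self.air_temperature = np.broadcast_to(
            np.asarray(self.air_temperature, dtype=float), (n,)).copy()
        self.pressure = np.broadcast_to(
            np.asarray(self.pressure, dtype=float), (n,)).copy()
        if self.wind_direction is not None:
            self.wind_direction = np.broadcast_to(
                np.asarray(self.wind_direction, dtype=float), (n,)).copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "wind_speed_m_s": self.wind_speed,
            "air_temp_k": self.air_temperature,
            "pressure_hpa": self.pressure,
        }, index=self.timestamps)
        if self.wind_direction is not None:
            df["wind_dir_deg"] = self.wind_direction
        return df


@dataclass(frozen=True)
class FluxResult:
    """Campaign-mean dry-deposition flux and its per-bin decomposition."""

    bin_midpoints: np.ndarray          # um
    deposition_velocity: np.ndarray    # m s-1, campaign-mean per bin
    mass_concentration: np.ndarray     # ug m-3, campaign-mean per bin
    bin_flux_daily: np.ndarray         # mg m-2 day-1 per bin
    total_daily: float                 # mg m-2 day-1
    n_steps: int

    @property
    def annualized(self) -> float:
        """Annual extrapolation of the campaign-mean daily rate (× 365)."""
        return self.total_daily * 365.0


# ---------------------------------------------------------------------------
# micro-physics

def slip_correction(d_um, mean_free_path_um: float = 0.0665):
    """Cunningham slip correction factor for particle diameter d (µm).

    Cc = 1 + (2λ/d)(1.257 + 0.4 exp(-1.1 d / 2λ)); always >= 1, tending to 1
    in the continuum (large-particle) limit.
    """
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0) or mean_free_path_um <= 0:
        raise ValueError("diameter and mean free path must be positive")
    kn2 = 2.0 * mean_free_path_um / d      # 2λ/d
    cc = 1.0 + kn2 * (1.257 + 0.4 * np.exp(-1.1 / kn2))
    return float(cc) if np.isscalar(d_um) else cc


def settling_velocity(d_um, params: DepositionParams,
                      temperature_k: float = DEFAULT_TEMPERATURE_K,
                      pressure_hpa: float = DEFAULT_PRESSURE_HPA):
    """Stokes terminal settling velocity (m s-1) with slip correction.

    v_g = Cc ρ_p d² g / (18 µ) with d converted to metres internally.
    """
    lam = params.mean_free_path(temperature_k, pressure_hpa)
    cc = slip_correction(d_um, lam)
    d_m = np.asarray(d_um, dtype=float) * 1e-6
    vg = cc * params.particle_density * d_m ** 2 * params.gravity \
        / (18.0 * params.air_viscosity)
    return float(vg) if np.isscalar(d_um) else vg


def friction_velocity(wind_speed: float, z: float, z0: float,
                      von_karman: float = 0.4) -> float:
    """Neutral log-profile friction velocity u* = κ U / ln(z/z0)."""
    if z0 <= 0 or z <= z0:
        raise ValueError("need z > z0 > 0")
    if wind_speed < 0:
        raise ValueError("wind speed must be non-negative")
    return von_karman * wind_speed / math.log(z / z0)


def deposition_velocity(d_um, wind_speed: float, params: DepositionParams,
                        z: float = 2.0,
                        temperature_k: float = DEFAULT_TEMPERATURE_K,
                        pressure_hpa: float = DEFAULT_PRESSURE_HPA):
    """Total dry-deposition velocity (m s-1) for diameter(s) d (µm).

    Settling in parallel with aerodynamic and quasi-laminar resistances in
    series.  In calm air (u* = 0) both resistances are infinite and the
    result reduces to the settling velocity alone.
    """
    vg = settling_velocity(d_um, params, temperature_k, pressure_hpa)
    ustar = friction_velocity(wind_speed, z, params.roughness_length,
                              params.von_karman)
    if ustar == 0.0:
        return vg
    d = np.asarray(d_um, dtype=float)
    lam = params.mean_free_path(temperature_k, pressure_hpa)
    cc = slip_correction(d, lam)
    rho_air = pressure_hpa * 100.0 / (R_SPECIFIC_AIR * temperature_k)
    nu = params.air_viscosity / rho_air                       # m2 s-1
    d_m = d * 1e-6
    diff_b = params.boltzmann * temperature_k * cc \
        / (3.0 * math.pi * params.air_viscosity * d_m)        # m2 s-1
    sc = nu / diff_b
    st = np.asarray(vg) * ustar ** 2 / (params.gravity * nu)
    r_a = math.log(z / params.roughness_length) / (params.von_karman * ustar)
    r_b = 1.0 / (ustar * (sc ** (-2.0 / 3.0) + 10.0 ** (-3.0 / st)))
    vd = vg + 1.0 / (r_a + r_b)
    return float(vd) if np.isscalar(d_um) else vd


# ---------------------------------------------------------------------------
# concentrations and fluxes

def number_concentration(counts, sample_flow: float, interval_min: float = 1.0):
    """Particle number concentration (m-3) from counts in one interval.

    counts / (flow [L min-1] × interval [min]) converted from per-litre to
    per-m³.
    """
    if sample_flow <= 0:
        raise ValueError("sample flow must be positive")
    if interval_min <= 0:
        raise ValueError("interval must be positive")
    c = np.asarray(counts, dtype=float)
    n = c / (sample_flow * interval_min) * 1000.0
    return float(n) if np.isscalar(counts) else n


def bin_mass_concentration(number_conc, d_mid_um, particle_density: float = 2650.0):
    """Mass concentration (µg m-3) of spheres of diameter d_mid at n m-3."""
    d_m = np.asarray(d_mid_um, dtype=float) * 1e-6
    mass_kg = (math.pi / 6.0) * d_m ** 3 * particle_density   # per particle
    m = np.asarray(number_conc, dtype=float) * mass_kg * 1e9  # kg -> ug
    return float(m) if np.isscalar(number_conc) and np.isscalar(d_mid_um) else m


def dry_flux(opc: OPCCampaign, met: MetSeries,
             params: DepositionParams | None = None,
             z: float | None = None,
             align_tolerance: str = "1min") -> FluxResult:
    """Campaign dry-deposition mass flux from OPC counts and meteorology.

    OPC and met records are joined on nearest timestamp within
    ``align_tolerance``; unmatched OPC steps are dropped.  Per matched step
    the flux is Σ_bins v_d(d_mid, met) · m_bin, and the campaign mean is
    expressed as mg m-2 day-1.
    """
    params = params or DepositionParams()
    if z is None:
        z = met.measurement_height
    left = pd.DataFrame({"t": opc.timestamps})
    right = met.to_frame().reset_index(names="t")
    joined = pd.merge_asof(left.sort_values("t"), right.sort_values("t"),
                           on="t", direction="nearest",
                           tolerance=pd.Timedelta(align_tolerance))
    ok = joined["wind_speed_m_s"].notna().to_numpy()
    if not ok.any():
        raise ValueError("no OPC timestamps align with the met series within tolerance")

    order = np.argsort(opc.timestamps.values)
    counts = opc.counts[order][ok]
    u = joined.loc[ok, "wind_speed_m_s"].to_numpy()
    t_k = joined.loc[ok, "air_temp_k"].to_numpy()
    p_hpa = joined.loc[ok, "pressure_hpa"].to_numpy()

    d_mid = opc.bin_midpoints
    nconc = number_concentration(counts, opc.sample_flow, opc.interval_min)
    mconc = bin_mass_concentration(nconc, d_mid[None, :], params.particle_density)

    # v_d varies per timestep through U, T, P; loop over unique met rows to
    # keep the evaluation cheap for long constant-weather stretches.
    met_keys = np.stack([u, t_k, p_hpa], axis=1)
    uniq, inv = np.unique(met_keys, axis=0, return_inverse=True)
    vd_table = np.empty((uniq.shape[0], d_mid.size))
    for i, (ui, ti, pi) in enumerate(uniq):
        vd_table[i] = deposition_velocity(d_mid, ui, params, z=z,
                                          temperature_k=ti, pressure_hpa=pi)
    vd = vd_table[inv]                       # (n_steps, n_bins), m s-1

    bin_flux_ug_s = vd * mconc               # ug m-2 s-1
    step_mean = bin_flux_ug_s.mean(axis=0)   # campaign mean per bin
    bin_daily = step_mean * 86400.0 / 1000.0  # mg m-2 day-1
    return FluxResult(
        bin_midpoints=d_mid,
        deposition_velocity=vd.mean(axis=0),
        mass_concentration=mconc.mean(axis=0),
        bin_flux_daily=bin_daily,
        total_daily=float(bin_daily.sum()),
        n_steps=int(ok.sum()),
    )


def wet_deposition_rate(load_mg_kg: float, precipitation_kg_m2_yr: float) -> float:
    """Particulate delivery via snowfall (mg m-2 yr-1): load × snowfall."""
    if load_mg_kg < 0 or precipitation_kg_m2_yr < 0:
        raise ValueError("load and precipitation must be non-negative")
    return load_mg_kg * precipitation_kg_m2_yr


def meltout_rate(ice_load_mg_kg: float, ablation_mwe_yr: float) -> float:
    """Particulate melt-out from ablating ice (mg m-2 yr-1).

    1 m water equivalent of ablation releases 1000 kg of meltwater per m².
    """
    if ice_load_mg_kg < 0 or ablation_mwe_yr < 0:
        raise ValueError("ice load and ablation must be non-negative")
    return ice_load_mg_kg * ablation_mwe_yr * 1000.0
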