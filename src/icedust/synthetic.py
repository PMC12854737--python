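"""Synthetic inputs with the statistical structure the pipeline assumes.

Every pipeline stage can be exercised offline: this module generates
per-particle diameter sets, OPC count time series, katabatic-regime
meteorology, snow-chemistry replicates, and taxon count tables whose
summary statistics emulate a melt-season field campaign on the southwest
Greenland Ice Sheet ablation zone (sub-µm silicate dust, south-easterly
katabatic winds near 4.7 m s-1, ~892 hPa, ~0 °C, fresh-snow particulate
loads of a few mg kg-1).

Diameters follow a lognormal law truncated at 17 µm — lognormal is the
standard working model for mineral aerosol size distributions, adopted
here as an assumption, not a claim about any particular data set; the
observed mean ± sd are mapped to (meanlog, sdlog) by moment matching.
OPC counts are Poisson per minute around bin-expected rates (independent
particle arrivals).  A single global seed governs all generators through
deterministic per-generator substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .deposition import MetSeries, OPCCampaign, default_bin_edges
from .geochem import SampleChemistry
from .particle_size import ParticleSet

__all__ = [
    "SyntheticSpec",
    "lognormal_params_from_moments",
    "lognormal_moments_from_params",
    "truncated_normal_mean",
    "gen_particle_set",
    "gen_opc_campaign",
    "gen_met_series",
    "gen_snow_samples",
    "gen_taxon_counts",
]


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(meanlog, sdlog) of the lognormal with given arithmetic mean and sd."""
    if mean <= 0 or sd < 0:
        raise ValueError("need mean > 0 and sd >= 0")
    if sd == 0:
        return math.log(mean), 0.0
    sdlog2 = math.log(1.0 + (sd / mean) ** 2)
    meanlog = math.log(mean) - 0.5 * sdlog2
    return meanlog, math.sqrt(sdlog2)


def lognormal_moments_from_params(meanlog: float, sdlog: float) -> tuple[float, float]:
    """Arithmetic (mean, sd) of lognormal(meanlog, sdlog)."""
    mean = math.exp(meanlog + 0.5 * sdlog ** 2)
    sd = mean * math.sqrt(math.exp(sdlog ** 2) - 1.0)
    return mean, sd


def truncated_normal_mean(mu: float, sd: float, lower: float = 0.0) -> float:
    """Mean of a normal(mu, sd) truncated below at ``lower``."""
    if sd == 0:
        return max(mu, lower)
    alpha = (lower - mu) / sd
    return mu + sd * stats.norm.pdf(alpha) / stats.norm.sf(alpha)


# meanlog/sdlog emulating the 2017 dry-deposition filter moments
# (mean 0.76 um, sd 0.87 um)
_DEFAULT_MEANLOG, _DEFAULT_SDLOG = lognormal_params_from_moments(0.76, 0.87)

_DEFAULT_TAXA: Mapping[str, float] = {
    "Proteobacteria": 0.35,
    "Bacteroidota": 0.20,
    "Actinobacteriota": 0.10,
    "Cyanobacteria": 0.08,
    "Firmicutes": 0.06,
    "Acidobacteriota": 0.05,
    "Planctomycetota": 0.05,
    "Verrucomicrobiota": 0.04,
    "Chloroflexi": 0.03,
    "Other": 0.04,
}

# substream keys: one fixed integer per generator, mixed with the global seed
_STREAMS = {"particles": 11, "opc": 23, "met": 37, "snow": 53, "taxa": 71}


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic campaign in one validated record.

    Defaults emulate the 2017 melt-season conditions: 0.76 ± 0.87 µm dust
    (lognormal by moment matching), 4.7 ± 1.9 m s-1 katabatic winds,
    892 ± 4 hPa, 0 ± 2.1 °C, fresh-snow loads near 2.9 mg kg-1 with
    dissolved P near 1.34 µg L-1, and a sub-µg m-3 airborne dust loading.
    """

    seed: int = 0
    n_particles: int = 10_000
    meanlog: float = _DEFAULT_MEANLOG
    sdlog: float = _DEFAULT_SDLOG
    diameter_cutoff: float = 17.0          # um
    campaign_days: int = 7
    storm_days: frozenset[int] = frozenset()
    mean_wind: float = 4.7                 # m s-1
    wind_sd: float = 1.9
    wind_dir_mean: float = 142.0           # deg (SE katabatic)
    wind_dir_sd: float = 43.1
    mean_pressure: float = 892.0           # hPa
    pressure_sd: float = 4.0
    mean_temp_c: float = 0.0
    temp_sd_c: float = 2.1
    measurement_height: float = 2.0        # m
    load_mean: float = 2.9                 # mg kg-1, fresh snow
    load_sd: float = 1.0
    dissolvedP_mean: float = 1.34          # ug L-1, fresh snow
    dissolvedP_sd: float = 0.3
    weathered_load_mean: float = 12.8      # mg kg-1
    weathered_load_sd: float = 4.5
    weathered_p_mean: float = 2.29         # ug L-1
    weathered_p_sd: float = 0.5
    dust_mass_ug_m3: float = 0.5           # target mean airborne mass loading
    sample_flow: float = 0.22              # L min-1
    taxon_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXA))

    def __post_init__(self):
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.sdlog < 0:
            raise ValueError("sdlog must be non-negative")
        for name in ("wind_sd", "pressure_sd", "temp_sd_c", "load_sd",
                     "dissolvedP_sd", "weathered_load_sd", "weathered_p_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.campaign_days < 0:
            raise ValueError("campaign_days must be non-negative")
        if self.diameter_cutoff <= 0 or self.dust_mass_ug_m3 < 0:
            raise ValueError("cutoff and dust loading must be positive")
        total = sum(self.taxon_profile.values())
        if self.taxon_profile and abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon profile must sum to 1 (got {total})")
        if any(p < 0 for p in self.taxon_profile.values()):
            raise ValueError("taxon proportions must be non-negative")

    def with_overrides(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-generator substream of the global seed."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------

def _truncated_lognormal(rng, meanlog, sdlog, cutoff, n):
    """n lognormal draws conditioned on <= cutoff (rejection sampling)."""
    if sdlog == 0:
        d = math.exp(meanlog)
        if d > cutoff:
            raise ValueError("degenerate diameter exceeds the cutoff")
        return np.full(n, d)
    out = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        draw = rng.lognormal(meanlog, sdlog, size=max(need, 64))
        draw = draw[draw <= cutoff][:need]
        out[filled:filled + draw.size] = draw
        filled += draw.size
    return out


def gen_particle_set(spec: SyntheticSpec) -> ParticleSet:
    """Lognormal equivalent-diameter sample truncated at the size cutoff."""
    rng = spec.rng("particles")
    d = _truncated_lognormal(rng, spec.meanlog, spec.sdlog,
                             spec.diameter_cutoff, spec.n_particles)
    areas = math.pi * (d / 2.0) ** 2
    return ParticleSet(diameters=d, areas=areas,
                       sample_id="synthetic", year=2017, source="filter_dry")


def _bin_probabilities(spec: SyntheticSpec, edges: np.ndarray) -> np.ndarray:
    """Lognormal probability mass per bin (unnormalized over the bin range)."""
    if spec.sdlog == 0:
        d = math.exp(spec.meanlog)
        p = np.zeros(edges.size - 1)
        idx = np.searchsorted(edges, d, side="right") - 1
        if 0 <= idx < p.size and d < edges[-1]:
            p[idx] = 1.0
        return p
    dist = stats.lognorm(s=spec.sdlog, scale=math.exp(spec.meanlog))
    cdf = dist.cdf(edges)
    return np.diff(cdf)


def expected_mass_per_particle_kg(spec: SyntheticSpec, edges: np.ndarray,
                                  particle_density: float = 2650.0) -> float:
    """Mean spherical particle mass (kg) over the binned size range.

    Uses the bin-midpoint (geometric mean) masses weighted by the bin
    probabilities — exactly the discretization the flux pipeline applies.
    """
    p = _bin_probabilities(spec, edges)
    if p.sum() == 0:
        raise ValueError("size distribution has no mass in the bin range")
    mid = np.sqrt(edges[:-1] * edges[1:]) * 1e-6
    mass = (math.pi / 6.0) * mid ** 3 * particle_density
    return float((p * mass).sum() / p.sum())


def gen_opc_campaign(spec: SyntheticSpec,
                     bin_edges: np.ndarray | None = None) -> OPCCampaign:
    """Per-minute Poisson OPC counts matching the spec's size distribution.

    Expected per-bin count rates are proportional to the lognormal
    probability mass in each bin; the overall rate is set so that the mean
    airborne mass concentration implied by the counts equals
    ``spec.dust_mass_ug_m3``.
    """
    edges = np.asarray(default_bin_edges() if bin_edges is None else bin_edges,
                       dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    minutes = spec.campaign_days * 24 * 60
    times = pd.date_range("2017-06-01", periods=minutes, freq="min")
    if minutes == 0:
        return OPCCampaign(timestamps=times, bin_edges=edges,
                           counts=np.zeros((0, edges.size - 1), dtype=np.int64),
                           sample_flow=spec.sample_flow)
    p = _bin_probabilities(spec, edges)
    p_range = p.sum()
    if p_range == 0:
        lam = np.zeros(edges.size - 1)
    else:
        mean_mass = expected_mass_per_particle_kg(spec, edges)
        n_total_m3 = spec.dust_mass_ug_m3 * 1e-9 / mean_mass    # particles m-3
        counts_per_min = n_total_m3 * spec.sample_flow / 1000.0  # sampled m3/min
        lam = counts_per_min * (p / p_range)
    rng = spec.rng("opc")
    counts = rng.poisson(lam=lam, size=(minutes, edges.size - 1))
    return OPCCampaign(timestamps=times, bin_edges=edges, counts=counts,
                       sample_flow=spec.sample_flow)


def gen_met_series(spec: SyntheticSpec) -> MetSeries:
    """One-minute meteorology with katabatic and storm-day regimes.

    Non-storm days: south-easterly winds, Gaussian speeds (truncated at 0)
    around ``mean_wind``, smooth near-mean pressure.  Storm days: westerly,
    slower winds and a pronounced pressure low.  Pressure is built from
    daily anchors (clipped to ±2.5 sd on calm days) interpolated to minutes,
    so calm-period pressure never dips 3 sd below the mean.
    """
    if spec.campaign_days <= 0:
        raise ValueError("campaign_days must be positive for a met series")
    rng = spec.rng("met")
    minutes = spec.campaign_days * 24 * 60
    times = pd.date_range("2017-06-01", periods=minutes, freq="min")
    day = np.arange(minutes) // (24 * 60)
    stormy = np.isin(day, list(spec.storm_days))

    speed = rng.normal(spec.mean_wind, spec.wind_sd, size=minutes)
    if spec.wind_sd > 0:  # resample negatives: truncated normal
        for _ in range(100):
            bad = speed < 0
            if not bad.any():
                break
            speed[bad] = rng.normal(spec.mean_wind, spec.wind_sd, size=bad.sum())
        speed = np.maximum(speed, 0.0)
    speed[stormy] *= 0.5  # stagnant storm flow

    direction = rng.normal(spec.wind_dir_mean, spec.wind_dir_sd, size=minutes) % 360.0
    direction[stormy] = rng.normal(270.0, 30.0, size=stormy.sum()) % 360.0

    anchors = rng.normal(spec.mean_pressure, spec.pressure_sd,
                         size=spec.campaign_days + 1)
    anchors = np.clip(anchors,
                      spec.mean_pressure - 2.5 * spec.pressure_sd,
                      spec.mean_pressure + 2.5 * spec.pressure_sd)
    anchor_days = np.arange(spec.campaign_days + 1)
    storm_idx = [d for d in spec.storm_days if 0 <= d <= spec.campaign_days]
    anchors[storm_idx] = spec.mean_pressure - 5.0 * spec.pressure_sd
    pressure = np.interp(np.arange(minutes) / (24 * 60), anchor_days, anchors)

    temp_c = rng.normal(spec.mean_temp_c, spec.temp_sd_c, size=minutes)
    return MetSeries(timestamps=times, wind_speed=speed,
                     measurement_height=spec.measurement_height,
                     air_temperature=temp_c + 273.15,
                     pressure=pressure, wind_direction=direction)


def _trunc_gauss(rng, mean, sd, n):
    x = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = x < 0
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=bad.sum())
    return np.maximum(x, 0.0)


def gen_snow_samples(spec: SyntheticSpec, n_fresh: int,
                     n_weathered: int) -> list[SampleChemistry]:
    """Fresh and weathered snow records with Gaussian loads/P truncated at 0."""
    if n_fresh < 0 or n_weathered < 0:
        raise ValueError("sample counts must be non-negative")
    rng = spec.rng("snow")
    out: list[SampleChemistry] = []
    fresh_load = _trunc_gauss(rng, spec.load_mean, spec.load_sd, n_fresh)
    fresh_p = _trunc_gauss(rng, spec.dissolvedP_mean, spec.dissolvedP_sd, n_fresh)
    for i in range(n_fresh):
        out.append(SampleChemistry(
            sample_id=f"FS-{i + 1:03d}", sample_type="fresh_snow",
            load_mg_kg=float(fresh_load[i]), dissolved_p_ug_l=float(fresh_p[i])))
    w_load = _trunc_gauss(rng, spec.weathered_load_mean, spec.weathered_load_sd,
                          n_weathered)
    w_p = _trunc_gauss(rng, spec.weathered_p_mean, spec.weathered_p_sd, n_weathered)
    for i in range(n_weathered):
        out.append(SampleChemistry(
            sample_id=f"WS-{i + 1:03d}", sample_type="weathered_snow",
            load_mg_kg=float(w_load[i]), dissolved_p_ug_l=float(w_p[i])))
    return out


def gen_taxon_counts(spec: SyntheticSpec, depth: int,
                     n_samples: int = 1) -> pd.DataFrame:
    """Multinomial taxon count table (samples × taxa), ``depth`` reads each."""
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not spec.taxon_profile:
        raise ValueError("taxon profile is empty")
    taxa = list(spec.taxon_profile)
    probs = np.array([spec.taxon_profile[t] for t in taxa], dtype=float)
    rng = spec.rng("taxa")
    counts = rng.multinomial(depth, probs, size=n_samples)
    return pd.DataFrame(counts, columns=taxa,
                        index=[f"S{i + 1:02d}" for i in range(n_samples)])
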