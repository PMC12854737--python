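"""Equivalent circular diameters and particle size-distribution summaries.

Particle sizes measured from 2-D projections (SEM image analysis) are
expressed as the diameter of a circle with the same area as the particle's
projection.  Descriptive statistics are computed after applying an upper
size cutoff (default 17 µm) so that filter-based microscopy statistics are
comparable with optical-particle-counter size ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParticleSet",
    "SizeSummary",
    "EmptySummaryError",
    "equivalent_diameter",
    "size_summary",
    "bin_histogram",
]

#: Sources a particle set can come from: dry-deposition filters, the
#: large-volume impinger (Coriolis) sampler, or melted snow samples.
PARTICLE_SOURCES = ("filter_dry", "coriolis", "fresh_snow", "weathered_snow")


class EmptySummaryError(ValueError):
    """No particles remain after the size cutoff; summary undefined."""


def equivalent_diameter(area):
    """Diameter (µm) of a circle whose area equals ``area`` (µm²).

    d = 2 * sqrt(area / pi).  Accepts a scalar or array; all areas must be
    strictly positive.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0) or np.any(~np.isfinite(a)):
        raise ValueError("particle area must be positive and finite")
    d = 2.0 * np.sqrt(a / math.pi)
    return float(d) if np.isscalar(area) or a.ndim == 0 else d


@dataclass
class ParticleSet:
    """Per-particle equivalent circular diameters with sample metadata."""

    diameters: np.ndarray
    sample_id: str = ""
    year: int | None = None
    source: str = "filter_dry"
    areas: np.ndarray | None = None

    def __post_init__(self):
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.ndim != 1:
            raise ValueError("diameters must be a 1-D array")
        if np.any(self.diameters <= 0) or np.any(~np.isfinite(self.diameters)):
            raise ValueError("all diameters must be positive and finite")
        if self.source not in PARTICLE_SOURCES:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {PARTICLE_SOURCES}"
            )
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float)
            if self.areas.shape != self.diameters.shape:
                raise ValueError("areas and diameters must have the same length")
            implied = 2.0 * np.sqrt(self.areas / math.pi)
            rel = np.abs(implied - self.diameters) / self.diameters
            if np.any(rel > 1e-9):
                i = int(np.argmax(rel))
                raise ValueError(
                    "area/diameter mismatch at index "
                    f"{i}: area {self.areas[i]} implies d={implied[i]:.9g} "
                    f"but diameter is {self.diameters[i]:.9g}"
                )

    def __len__(self) -> int:
        return self.diameters.size


@dataclass(frozen=True)
class SizeSummary:
    """Descriptive statistics of a particle set after an upper size cutoff.

    ``fractions`` maps each threshold (µm) to the proportion of retained
    particles strictly below it.
    """

    n: int
    mean: float
    sd: float
    fractions: Mapping[float, float] = field(default_factory=dict)
    cutoff: float = 17.0


def size_summary(
    particles: ParticleSet,
    cutoff: float = 17.0,
    thresholds: Sequence[float] = (1.0, 5.0),
) -> SizeSummary:
    """Mean, sample sd and sub-threshold fractions of diameters <= cutoff.

    Particles larger than ``cutoff`` are dropped first.  The standard
    deviation uses the n-1 denominator; fractions count particles strictly
    below each threshold.  Raises :class:`EmptySummaryError` if nothing
    survives the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    d = particles.diameters
    kept = d[d <= cutoff]
    if kept.size == 0:
        raise EmptySummaryError(
            f"no particles at or below the {cutoff} um cutoff (input n={d.size})"
        )
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else float("nan")
    fractions = {float(t): float(np.mean(kept < t)) for t in thresholds}
    return SizeSummary(n=int(kept.size), mean=mean, sd=sd,
                       fractions=fractions, cutoff=float(cutoff))


def bin_histogram(particles: ParticleSet, edges: Sequence[float]) -> np.ndarray:
    """Counts per half-open bin [e_i, e_{i+1}).

    Particles outside [edges[0], edges[-1]) are excluded (never silently
    folded into the end bins), so the histogram total plus the number of
    out-of-range particles equals ``len(particles)``.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d = particles.diameters
    idx = np.searchsorted(edges, d, side="right") - 1
    valid = (idx >= 0) & (idx < edges.size - 1) & (d >= edges[0]) & (d < edges[-1])
    counts = np.bincount(idx[valid], minlength=edges.size - 1)
    return counts.astype(np.int64)
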