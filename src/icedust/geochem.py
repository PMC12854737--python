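"""Rare-earth-element normalization, Eu anomaly, and meltwater chemistry.

REE patterns are normalized element-wise against a reference composition
(CI chondrite or upper continental crust shipped with the package, or any
user-supplied reference).  The europium anomaly Eu/Eu* compares normalized
Eu against the value interpolated between its neighbours Sm and Gd; values
above 1 indicate Eu enrichment (a provenance fingerprint of
feldspar-bearing source rocks).  Meltwater chemistry summaries group sample
records by type and report per-analyte mean, sd and n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SampleChemistry",
    "REE_ELEMENTS",
    "SAMPLE_TYPES",
    "load_reference",
    "normalize_ree",
    "eu_anomaly",
    "chemistry_summary",
]

REE_ELEMENTS = ("La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
                "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu")

SAMPLE_TYPES = ("fresh_snow", "weathered_snow", "clean_surface_ice", "core_ice")

_REFERENCE_FILES = {"chondrite_ci": "chondrite_ci.csv", "ucc": "ucc.csv"}


@dataclass
class SampleChemistry:
    """One melted snow/ice sample: particulate load and dissolved chemistry."""

    sample_id: str
    sample_type: str
    load_mg_kg: float | None = None
    dissolved_p_ug_l: float | None = None
    ions_ug_l: Mapping[str, float] = field(default_factory=dict)
    ph: float | None = None
    conductivity_us_cm: float | None = None
    tds_mg_l: float | None = None

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample type {self.sample_type!r}; expected one of {SAMPLE_TYPES}")
        for name, v in (("load_mg_kg", self.load_mg_kg),
                        ("dissolved_p_ug_l", self.dissolved_p_ug_l)):
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.ions_ug_l.values()):
            raise ValueError("ion concentrations must be non-negative")


def load_reference(name: str = "chondrite_ci") -> dict[str, float]:
    """Load a shipped REE normalizing reference ('chondrite_ci' or 'ucc')."""
    try:
        fname = _REFERENCE_FILES[name]
    except KeyError:
        raise ValueError(
            f"unknown reference {name!r}; available: {sorted(_REFERENCE_FILES)}") from None
    with resources.files("icedust.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["element"], df["concentration_ug_g"].astype(float)))


def normalize_ree(pattern: Mapping[str, float],
                  reference: Mapping[str, float] | str = "chondrite_ci"
                  ) -> dict[str, float]:
    """Element-wise sample/reference concentration ratios.

    Every element in ``pattern`` must exist in the reference with a strictly
    positive concentration.
    """
    if isinstance(reference, str):
        reference = load_reference(reference)
    out: dict[str, float] = {}
    for el, conc in pattern.items():
        if el not in reference:
            raise KeyError(f"reference has no concentration for element {el}")
        ref = reference[el]
        if ref <= 0:
            raise ValueError(f"reference concentration for {el} must be positive")
        if conc < 0:
            raise ValueError(f"sample concentration for {el} must be non-negative")
        out[el] = conc / ref
    return out


def eu_anomaly(normalized: Mapping[str, float], method: str = "geometric") -> float:
    """Eu/Eu* from a normalized REE pattern.

    ``geometric`` (standard): Eu* = sqrt(Sm_N · Gd_N).
    ``arithmetic``: Eu* = (Sm_N + Gd_N) / 2.
    Values > 1 are a positive anomaly.
    """
    missing = [el for el in ("Sm", "Eu", "Gd") if el not in normalized]
    if missing:
        raise KeyError(f"normalized pattern missing element(s): {missing}")
    sm, eu, gd = (normalized[el] for el in ("Sm", "Eu", "Gd"))
    if min(sm, eu, gd) <= 0:
        raise ValueError("Sm, Eu and Gd must be strictly positive")
    if method == "geometric":
        star = math.sqrt(sm * gd)
    elif method == "arithmetic":
        star = 0.5 * (sm + gd)
    else:
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    return eu / star


def chemistry_summary(samples: Iterable[SampleChemistry]) -> pd.DataFrame:
    """Per-sample-type mean, sd and n for each analyte.

    Returns a long-format frame with columns sample_type, analyte, mean, sd,
    n.  Groups with a single observation report sd as NaN (undefined).
    Analytes are the particulate load, dissolved P, and every major ion
    present in any sample.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    records = []
    for s in samples:
        row = {"sample_type": s.sample_type,
               "load_mg_kg": s.load_mg_kg,
               "dissolved_p_ug_l": s.dissolved_p_ug_l}
        for ion, v in s.ions_ug_l.items():
            row[f"ion_{ion}_ug_l"] = v
        records.append(row)
    df = pd.DataFrame.from_records(records)
    analytes = [c for c in df.columns if c != "sample_type"]
    out = []
    for (stype, analyte), grp in (
            df.melt(id_vars="sample_type", value_vars=analytes,
                    var_name="analyte").dropna(subset=["value"])
            .groupby(["sample_type", "analyte"], sort=True)):
        vals = grp["value"].to_numpy(dtype=float)
        out.append({
            "sample_type": stype,
            "analyte": analyte,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
            "n": int(vals.size),
        })
    return pd.DataFrame(out)
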