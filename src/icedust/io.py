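"""CSV/TSV readers and writers for the pipeline's tabular interfaces.

Every reader validates the corresponding domain-type invariants on load and
reports violations with the offending row number.  Writers emit the same
dialects the readers accept, so synthetic runs exercise the real I/O path.

Formats
-------
particles : sample_id, year, source, area_um2 and/or diameter_um
opc       : timestamp (ISO-8601), flow_l_min, one ``bin_<lo>_<hi>`` column
            per size bin (the header encodes the bin edges in µm)
met       : timestamp, wind_speed_m_s, height_m, air_temp_c, pressure_hpa
            [, wind_dir_deg]
chemistry : sample_id, type, load_mg_kg, dissolved_p_ug_l [, ion_*_ug_l ...]
ree       : element, concentration_ug_g
taxa      : TSV, taxa as rows and samples as columns
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .deposition import MetSeries, OPCCampaign
from .geochem import SampleChemistry
from .particle_size import ParticleSet

__all__ = [
    "read_particles", "write_particles",
    "read_opc", "write_opc",
    "read_met", "write_met",
    "read_chemistry", "write_chemistry",
    "read_ree", "write_ree",
    "read_taxa", "write_taxa",
]

_BIN_RE = re.compile(r"^bin_([0-9.eE+-]+)_([0-9.eE+-]+)$")


class TableFormatError(ValueError):
    """A tabular input violates its format contract."""


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def read_particles(path) -> ParticleSet:
    df = pd.read_csv(path)
    if "diameter_um" not in df.columns and "area_um2" not in df.columns:
        raise TableFormatError(f"{path}: need diameter_um and/or area_um2")
    areas = df["area_um2"].to_numpy(float) if "area_um2" in df.columns else None
    if "diameter_um" in df.columns:
        d = df["diameter_um"].to_numpy(float)
    else:
        d = 2.0 * np.sqrt(areas / math.pi)
    bad = np.flatnonzero(~(d > 0) | ~np.isfinite(d))
    if bad.size:
        raise TableFormatError(
            f"{path}: non-positive diameter at data row {bad[0] + 1}")
    meta = {}
    for col, key in (("sample_id", "sample_id"), ("year", "year"),
                     ("source", "source")):
        if col in df.columns and df[col].nunique() == 1:
            meta[key] = df[col].iloc[0]
    if "year" in meta:
        meta["year"] = int(meta["year"])
    return ParticleSet(diameters=d, areas=areas, **meta)


def write_particles(ps: ParticleSet, path) -> None:
    df = pd.DataFrame({"sample_id": ps.sample_id, "year": ps.year,
                       "source": ps.source, "diameter_um": ps.diameters})
    if ps.areas is not None:
        df["area_um2"] = ps.areas
    df.to_csv(path, index=False)


def read_opc(path) -> OPCCampaign:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require(df, ["timestamp", "flow_l_min"], path)
    bins = []
    for c in df.columns:
        m = _BIN_RE.match(c)
        if m:
            bins.append((float(m.group(1)), float(m.group(2)), c))
    if not bins:
        raise TableFormatError(f"{path}: no bin_<lo>_<hi> columns found")
    bins.sort()
    edges = [bins[0][0]]
    for lo, hi, _ in bins:
        if not math.isclose(lo, edges[-1], rel_tol=1e-9):
            raise TableFormatError(
                f"{path}: bin edges in header are not contiguous at {lo}")
        edges.append(hi)
    counts = df[[c for _, _, c in bins]].to_numpy()
    neg = np.argwhere(counts < 0)
    if neg.size:
        r, c = neg[0]
        raise TableFormatError(f"{path}: negative count at data row {r + 1}")
    flow = df["flow_l_min"].to_numpy(float)
    if flow.size and not np.allclose(flow, flow[0]):
        raise TableFormatError(f"{path}: sample flow must be constant")
    return OPCCampaign(timestamps=pd.DatetimeIndex(df["timestamp"]),
                       bin_edges=np.asarray(edges),
                       counts=counts.astype(np.int64),
                       sample_flow=float(flow[0]) if flow.size else 0.22)


def write_opc(opc: OPCCampaign, path) -> None:
    cols = {
        f"bin_{lo:g}_{hi:g}": opc.counts[:, i]
        for i, (lo, hi) in enumerate(zip(opc.bin_edges[:-1], opc.bin_edges[1:]))
    }
    df = pd.DataFrame({"timestamp": opc.timestamps,
                       "flow_l_min": opc.sample_flow, **cols})
    df.to_csv(path, index=False)


def read_met(path) -> MetSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require(df, ["timestamp", "wind_speed_m_s", "height_m",
                  "air_temp_c", "pressure_hpa"], path)
    u = df["wind_speed_m_s"].to_numpy(float)
    bad = np.flatnonzero(u < 0)
    if bad.size:
        raise TableFormatError(
            f"{path}: negative wind speed at data row {bad[0] + 1}")
    return MetSeries(
        timestamps=pd.DatetimeIndex(df["timestamp"]),
        wind_speed=u,
        measurement_height=float(df["height_m"].iloc[0]),
        air_temperature=df["air_temp_c"].to_numpy(float) + 273.15,
        pressure=df["pressure_hpa"].to_numpy(float),
        wind_direction=(df["wind_dir_deg"].to_numpy(float)
                        if "wind_dir_deg" in df.columns else None),
    )


def write_met(met: MetSeries, path) -> None:
    df = pd.DataFrame({
        "timestamp": met.timestamps,
        "wind_speed_m_s": met.wind_speed,
        "height_m": met.measurement_height,
        "air_temp_c": np.asarray(met.air_temperature) - 273.15,
        "pressure_hpa": met.pressure,
    })
    if met.wind_direction is not None:
        df["wind_dir_deg"] = met.wind_direction
    df.to_csv(path, index=False)


def read_chemistry(path) -> list[SampleChemistry]:
    df = pd.read_csv(path)
    _require(df, ["sample_id", "type"], path)
    ion_cols = [c for c in df.columns if c.startswith("ion_") and c.endswith("_ug_l")]
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SampleChemistry(
                sample_id=str(row["sample_id"]),
                sample_type=str(row["type"]),
                load_mg_kg=(None if pd.isna(row.get("load_mg_kg"))
                            else float(row["load_mg_kg"])),
                dissolved_p_ug_l=(None if pd.isna(row.get("dissolved_p_ug_l"))
                                  else float(row["dissolved_p_ug_l"])),
                ions_ug_l={c[4:-5]: float(row[c]) for c in ion_cols
                           if not pd.isna(row[c])},
            ))
        except ValueError as e:
            raise TableFormatError(f"{path}: data row {i + 1}: {e}") from e
    return out


def write_chemistry(samples: list[SampleChemistry], path) -> None:
    ions = sorted({ion for s in samples for ion in s.ions_ug_l})
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "type": s.sample_type,
               "load_mg_kg": s.load_mg_kg, "dissolved_p_ug_l": s.dissolved_p_ug_l}
        for ion in ions:
            row[f"ion_{ion}_ug_l"] = s.ions_ug_l.get(ion)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ree(path) -> dict[str, float]:
    df = pd.read_csv(path, comment="#")
    _require(df, ["element", "concentration_ug_g"], path)
    return dict(zip(df["element"], df["concentration_ug_g"].astype(float)))


def write_ree(pattern: dict[str, float], path) -> None:
    pd.DataFrame({"element": list(pattern),
                  "concentration_ug_g": list(pattern.values())}
                 ).to_csv(path, index=False)


def read_taxa(path) -> pd.DataFrame:
    """TSV with taxa as rows and samples as columns → samples × taxa frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise TableFormatError(f"{path}: negative taxon counts")
    return df.T


def write_taxa(table: pd.DataFrame, path) -> None:
    """samples × taxa frame → TSV with taxa as rows, samples as columns."""
    table.T.to_csv(path, sep="\t")


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
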