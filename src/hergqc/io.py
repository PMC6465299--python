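"""CSV schemas and provenance-carrying readers/writers for all assay tables.

Every output file starts with ``# key: value`` provenance comment lines
(package version, seed, preset hash, time unit where relevant) followed by an
exact lowercase header. Readers validate headers, numeric cells and duplicate
keys, and fail loudly on empty files; a write -> read round trip is lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .params import ParameterError
from .simulate import ChxCourse, PulseChaseTable, RecyclingTable, SurfaceTimeCourse, VesicleSet

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_assay_csv",
    "write_assay_csv",
    "write_pulse_chase",
    "read_pulse_chase",
    "write_surface",
    "read_surface",
    "write_recycling",
    "read_recycling",
    "write_vesicles",
    "read_vesicles",
    "write_chx",
    "read_chx",
]


class SchemaError(ParameterError):
    """Raised when an assay CSV violates its declared schema."""


#: assay name -> (ordered headers, key columns that must be unique together)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "pulse_chase": (
        ("replicate", "chase_time_h", "cg_intensity", "fg_intensity"),
        ("replicate", "chase_time_h"),
    ),
    "surface": (("time", "well", "signal", "is_background"), ("time", "well")),
    "recycling": (("pool_signal", "time_min", "recycled_signal"), ("time_min",)),
    "vesicles": (("chase_time_h", "ph"), ()),
    "chx": (("temp_c", "time_h", "mature", "immature"), ("temp_c", "time_h")),
}

_NON_NUMERIC = {"well", "is_background"}


def write_assay_csv(
    df: pd.DataFrame, path: str | Path, assay: str, provenance: dict | None = None
) -> Path:
    """Write an assay table with provenance header comments."""
    if assay not in SCHEMAS:
        raise SchemaError(f"unknown assay {assay!r}; known: {sorted(SCHEMAS)}")
    columns, _ = SCHEMAS[assay]
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{assay}: missing columns {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (provenance or {}).items():
        buf.write(f"# {key}: {value}\n")
    df[list(columns)].to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def _read_provenance(path: Path) -> dict[str, str]:
    prov = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                prov[key.strip()] = value.strip()
    return prov


def read_assay_csv(path: str | Path, assay: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read and validate an assay CSV; returns (table, provenance)."""
    if assay not in SCHEMAS:
        raise SchemaError(f"unknown assay {assay!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    columns, keys = SCHEMAS[assay]
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    if tuple(df.columns) != columns:
        raise SchemaError(
            f"{path}: header mismatch; expected {','.join(columns)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    for col in columns:
        if col in _NON_NUMERIC:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(f"{path}: non-numeric value in column {col!r} near line {row}")
        df[col] = numeric
    if keys and df.duplicated(subset=list(keys)).any():
        raise SchemaError(f"{path}: duplicate {'/'.join(keys)} keys")
    return df, _read_provenance(path)


def write_pulse_chase(table: PulseChaseTable, path, provenance=None) -> Path:
    df = table.data.rename(columns={})
    return write_assay_csv(df, path, "pulse_chase", provenance)


def read_pulse_chase(path) -> PulseChaseTable:
    df, _ = read_assay_csv(path, "pulse_chase")
    return PulseChaseTable(df)


def write_surface(tc: SurfaceTimeCourse, path, provenance=None) -> Path:
    prov = dict(provenance or {})
    prov.setdefault("time_unit", tc.time_unit)
    return write_assay_csv(tc.data, path, "surface", prov)


def read_surface(path) -> SurfaceTimeCourse:
    df, prov = read_assay_csv(path, "surface")
    if df["is_background"].dtype == object:
        df["is_background"] = df["is_background"].astype(str).str.lower().eq("true")
    return SurfaceTimeCourse(df, time_unit=prov.get("time_unit", "min"))


def write_recycling(rt: RecyclingTable, path, provenance=None) -> Path:
    df = rt.data.copy()
    df.insert(0, "pool_signal", rt.pool_signal)
    prov = dict(provenance or {})
    prov.setdefault("block_efficiency", rt.block_efficiency)
    return write_assay_csv(df, path, "recycling", prov)


def read_recycling(path) -> RecyclingTable:
    df, prov = read_assay_csv(path, "recycling")
    pools = df["pool_signal"].unique()
    if pools.size != 1:
        raise SchemaError(f"{path}: pool_signal must be constant")
    return RecyclingTable(
        pool_signal=float(pools[0]),
        data=df[["time_min", "recycled_signal"]],
        block_efficiency=float(prov.get("block_efficiency", 0.99)),
    )


def write_vesicles(vs: VesicleSet, path, provenance=None) -> Path:
    df = pd.DataFrame({"chase_time_h": vs.chase_time_h, "ph": vs.ph_values})
    return write_assay_csv(df, path, "vesicles", provenance)


def read_vesicles(path) -> list[VesicleSet]:
    """One VesicleSet per distinct chase time in the file."""
    df, _ = read_assay_csv(path, "vesicles")
    return [
        VesicleSet(chase_time_h=float(t), ph_values=g["ph"].to_numpy())
        for t, g in df.groupby("chase_time_h")
    ]


def write_chx(courses: list[ChxCourse], path, provenance=None) -> Path:
    frames = []
    for c in courses:
        df = c.data.copy()
        df.insert(0, "temp_c", c.temperature)
        frames.append(df)
    return write_assay_csv(pd.concat(frames, ignore_index=True), path, "chx", provenance)


def read_chx(path) -> list[ChxCourse]:
    df, _ = read_assay_csv(path, "chx")
    return [
        ChxCourse(temperature=float(t), data=g[["time_h", "mature", "immature"]].reset_index(drop=True))
        for t, g in df.groupby("temp_c")
    ]
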