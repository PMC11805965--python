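"""Readers and writers for the tabular and spatial data the pipeline consumes.

Every table is carried in memory as a plain :class:`pandas.DataFrame` with a
canonical column set; :func:`read_table` validates files against a named
schema (accepting common vendor-export synonyms for each column) and
:func:`write_table` serializes back losslessly, timestamps in one canonical
UTC format with 1-second resolution.

Schemas
-------
``detections``   one row per logged tag transmission per receiver
``receivers``    receiver deployment metadata (projected meters)
``positions``    triangulated positions with HPE error sensitivity
``environment``  one row per calendar date (pressure, temperature, tilt)
``relocations``  recaptures and glider detections outside the array
``coas``         time-binned centers of activity
``fates``        per-fish terminal classifications
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

log = logging.getLogger("reeftrack")

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%SZ"
DATE_FORMAT = "%Y-%m-%d"


class SchemaError(ValueError):
    """A file's header or rows do not match the requested schema."""


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # str | float | int | datetime | date | bool
    required: bool = True
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class Schema:
    name: str
    columns: tuple[Column, ...]
    dedup_on: tuple[str, ...] = ()

    @property
    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]


SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in [
        Schema(
            "detections",
            (
                Column("tag_id", "str", synonyms=("transmitter", "tag", "transmitter_id")),
                Column("receiver_id", "str", synonyms=("receiver", "station")),
                Column("timestamp", "datetime", synonyms=("datetime", "date_time", "detection_timestamp_utc")),
                Column("depth_m", "float", required=False, synonyms=("depth", "sensor_depth")),
            ),
            dedup_on=("tag_id", "receiver_id", "timestamp"),
        ),
        Schema(
            "receivers",
            (
                Column("receiver_id", "str", synonyms=("receiver", "station_id")),
                Column("x_m", "float", synonyms=("x", "easting")),
                Column("y_m", "float", synonyms=("y", "northing")),
                Column("deploy_date", "date", synonyms=("deployed", "deploy")),
                Column("recover_date", "date", synonyms=("recovered", "recover")),
                Column("station_name", "str", required=False),
                Column("array_label", "str", required=False, synonyms=("array",)),
                Column("habitat_label", "str", required=False, synonyms=("habitat",)),
            ),
        ),
        Schema(
            "positions",
            (
                Column("tag_id", "str", synonyms=("transmitter", "tag")),
                Column("timestamp", "datetime", synonyms=("datetime", "date_time")),
                Column("x_m", "float", synonyms=("x", "easting")),
                Column("y_m", "float", synonyms=("y", "northing")),
                Column("hpe", "float", synonyms=("HPE",)),
                Column("known_x_m", "float", required=False),
                Column("known_y_m", "float", required=False),
                Column("depth_m", "float", required=False, synonyms=("depth",)),
            ),
        ),
        Schema(
            "environment",
            (
                Column("date", "date"),
                Column("atm_pressure_mbar", "float", synonyms=("pressure", "atm_pressure", "pressure_mbar")),
                Column("bottom_temp_C", "float", required=False, synonyms=("temperature", "bottom_temp")),
                Column("tilt_deg", "float", required=False, synonyms=("tilt",)),
            ),
        ),
        Schema(
            "relocations",
            (
                Column("tag_id", "str", synonyms=("transmitter", "tag")),
                Column("timestamp", "datetime", synonyms=("datetime",)),
                Column("x_m", "float", required=False),
                Column("y_m", "float", required=False),
                Column("lon", "float", required=False, synonyms=("longitude",)),
                Column("lat", "float", required=False, synonyms=("latitude",)),
                Column("source", "str"),
                Column("alive", "bool"),
            ),
        ),
        Schema(
            "coas",
            (
                Column("tag_id", "str"),
                Column("bin_start", "datetime"),
                Column("bin_minutes", "int"),
                Column("x_m", "float"),
                Column("y_m", "float"),
                Column("n_receivers", "int"),
                Column("mean_depth_m", "float", required=False),
            ),
        ),
        Schema(
            "fates",
            (
                Column("tag_id", "str"),
                Column("fate", "str"),
                Column("ctr_flag", "bool"),
                Column("fate_date", "date"),
                Column("tag_date", "date"),
                Column("evidence", "str", required=False),
                Column("confirmed_by", "str", required=False),
            ),
        ),
        Schema(
            "event_histories",
            (
                Column("tag_id", "str"),
                Column("time_days", "float"),
                Column("event", "bool"),
                Column("fate_source", "str", required=False),
                Column("unknown_treatment", "str", required=False),
            ),
        ),
    ]
}


def _resolve_header(header: list[str], schema: Schema) -> dict[str, str]:
    lookup: dict[str, str] = {}
    for col in schema.columns:
        accepted = {col.name.lower()} | {s.lower() for s in col.synonyms}
        for h in header:
            if h.strip().lower() in accepted:
                lookup[h] = col.name
                break
    mapped = set(lookup.values())
    missing = [c.name for c in schema.columns if c.required and c.name not in mapped]
    if missing:
        accepted_list = {
            c.name: [c.name, *c.synonyms] for c in schema.columns if c.name in missing
        }
        raise SchemaError(
            f"schema '{schema.name}': missing required column(s) {missing}; "
            f"accepted names: {accepted_list}; file header: {header}"
        )
    return lookup


def _parse_column(series: pd.Series, col: Column, path) -> pd.Series:
    if col.kind == "datetime":
        parsed = pd.to_datetime(series, utc=True, errors="coerce", format="mixed")
        bad = parsed.isna() & series.notna() & (series.astype(str).str.len() > 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise SchemaError(
                f"{path}: unparseable timestamp {series[bad.idxmax()]!r} in column "
                f"'{col.name}' at line {line}"
            )
        return parsed.dt.floor("s")
    if col.kind == "date":
        parsed = pd.to_datetime(series, errors="coerce", format="mixed")
        bad = parsed.isna() & series.notna() & (series.astype(str).str.len() > 0)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SchemaError(f"{path}: unparseable date in '{col.name}' at line {line}")
        return parsed.dt.normalize()
    if col.kind in ("float", "int"):
        out = pd.to_numeric(series, errors="coerce")
        return out.astype(float) if col.kind == "float" else out.astype("Int64")
    if col.kind == "bool":
        return series.astype(str).str.strip().str.lower().isin(("true", "1", "t", "yes"))
    return series.astype("string")


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Duplicate rows on the schema's dedup key are dropped and counted in a
    warning. Unknown required columns raise :class:`SchemaError` listing the
    accepted names; a malformed timestamp raises with its line number.
    """
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    lookup = _resolve_header(list(raw.columns), schema)
    df = raw.rename(columns=lookup)
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        if col.name in df.columns:
            out[col.name] = _parse_column(df[col.name], col, path)
        elif col.required:
            raise SchemaError(f"{path}: missing column {col.name}")
        else:
            out[col.name] = np.nan
    if schema.dedup_on:
        before = len(out)
        out = out.drop_duplicates(subset=list(schema.dedup_on), keep="first")
        dropped = before - len(out)
        if dropped:
            warnings.warn(f"{path}: dropped {dropped} duplicate row(s)", stacklevel=2)
            log.info("read_table(%s): dropped %d duplicate rows", path, dropped)
    if schema_name == "detections":
        out = out.sort_values(["tag_id", "receiver_id", "timestamp"], kind="stable")
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, schema_name: str) -> None:
    """Serialize a table in the canonical CSV dialect (UTF-8, ISO-8601 UTC)."""
    schema = SCHEMAS[schema_name]
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        if col.name not in df.columns:
            continue
        s = df[col.name]
        if col.kind == "datetime":
            s = pd.to_datetime(s, utc=True).dt.strftime(TIMESTAMP_FORMAT)
        elif col.kind == "date":
            s = pd.to_datetime(s).dt.strftime(DATE_FORMAT)
        out[col.name] = s
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Habitat maps (GeoJSON)
# ---------------------------------------------------------------------------

HABITAT_LABELS = ("HB", "ledge", "AR", "sand")


@dataclass
class HabitatMap:
    """Named habitat polygons in the projected meter frame.

    ``sand`` is implicit: any point not inside a named polygon.
    """

    polygons: dict[str, Polygon] = field(default_factory=dict)

    def label(self, x: float, y: float) -> str:
        p = Point(x, y)
        for name, poly in self.polygons.items():
            if poly.contains(p) or poly.touches(p):
                return name
        return "sand"

    def to_geojson(self, path) -> None:
        features = [
            {"type": "Feature", "properties": {"habitat_label": name},
             "geometry": mapping(poly)}
            for name, poly in self.polygons.items()
        ]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        )

    @classmethod
    def from_geojson(cls, path) -> "HabitatMap":
        data = json.loads(Path(path).read_text())
        polys = {}
        for feat in data["features"]:
            geom = shape(feat["geometry"])
            if not geom.is_valid:
                raise SchemaError(f"{path}: invalid (self-intersecting?) polygon")
            polys[feat["properties"]["habitat_label"]] = geom
        return cls(polys)


# ---------------------------------------------------------------------------
# key=value configuration files
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Parse a plain-text key=value config; values are int/float/bool/str."""
    cfg: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        cfg[key] = _coerce(value)
    return cfg


def _coerce(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def write_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in sorted(cfg.items())))
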