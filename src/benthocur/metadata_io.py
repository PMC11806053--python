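"""Read, validate, impute and write seafloor-image metadata tables.

The schema is the published compilation format: one CSV row per image with
columns ``url, source, dataset, site, image, latitude, longitude, datetime``
plus optional environmental columns (``gebco_bathymetry``, ``emu``); the
labelled variant adds the partition, annotation-point, original-label,
CATAMI-path, qualifier and AphiaID columns.  Missing values are empty
strings on disk; datetimes are ``YYYY-MM-DD HH:mm:ss`` in UTC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import geo

#: mandatory columns for unlabelled-compilation metadata
UNLABELLED_COLUMNS = ["url", "source", "dataset", "site", "image",
                      "latitude", "longitude", "datetime"]
#: optional environmental-join columns
ENV_COLUMNS = ["gebco_bathymetry", "emu"]
#: additional columns for labelled-compilation metadata
LABELLED_EXTRA_COLUMNS = ["partition", "annotation_column", "annotation_row",
                          "original_label", "catami_biota", "catami_substrate",
                          "catami_bedforms", "catami_relief",
                          "catami_qualifiers", "colour_qualifier",
                          "bleached", "dead", "aphia_id"]
LABELLED_COLUMNS = UNLABELLED_COLUMNS + LABELLED_EXTRA_COLUMNS

CATAMI_COLUMNS = ["catami_biota", "catami_substrate",
                  "catami_bedforms", "catami_relief"]

KEY_COLUMNS = ["dataset", "site", "image"]

DATETIME_FORMAT = "%Y-%m-%d %H:%M:%S"

_FLOAT_COLUMNS = ["latitude", "longitude", "annotation_column",
                  "annotation_row", "bleached", "dead", "gebco_bathymetry"]
_INT_LIKE_COLUMNS = ["aphia_id", "emu"]


class SchemaError(ValueError):
    """Raised when a metadata table does not conform to the schema."""


def read_records(path, labelled: bool = False,
                 strict_ranges: bool = True) -> pd.DataFrame:
    """Read a metadata CSV into a DataFrame, validating the schema.

    Unknown columns are preserved untouched; missing mandatory columns raise
    :class:`SchemaError` naming them.  Numeric columns are parsed; a value
    that fails to parse raises with its row number.  With
    ``strict_ranges=False`` out-of-range coordinates are loaded as-is so
    :func:`validate_records` can report them instead.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = LABELLED_COLUMNS if labelled else UNLABELLED_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    for col in _FLOAT_COLUMNS + _INT_LIKE_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col].mask(df[col] == "")
        try:
            df[col] = raw.astype(float)
        except ValueError:
            bad = raw[~raw.isna() & pd.to_numeric(raw, errors="coerce").isna()]
            row = int(bad.index[0])
            raise SchemaError(
                f"unparseable value {bad.iloc[0]!r} in column {col!r}, "
                f"row {row}") from None
    if strict_ranges:
        _check_ranges(df)
    return df


def _check_ranges(df: pd.DataFrame) -> None:
    for col, lo, hi in [("latitude", -90, 90), ("longitude", -180, 180),
                        ("annotation_column", 0, 1), ("annotation_row", 0, 1)]:
        if col not in df.columns or not np.issubdtype(df[col].dtype, np.number):
            continue
        bad = df.index[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            raise SchemaError(
                f"{col} out of range [{lo}, {hi}] at row {int(bad[0])}")


def write_records(df: pd.DataFrame, path) -> None:
    """Write a metadata table back to CSV (empty strings for missing)."""
    out = df.copy()
    for col in _INT_LIKE_COLUMNS:
        if col in out.columns and np.issubdtype(out[col].dtype, np.number):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(int(v))
                if float(v).is_integer() else repr(v))
    out.to_csv(path, index=False, na_rep="")


@dataclass
class ValidationFinding:
    kind: str
    row: int | None
    column: str | None
    message: str

    def to_dict(self) -> dict:
        return {"kind": self.kind, "row": self.row,
                "column": self.column, "message": self.message}


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    def add(self, kind, row, column, message):
        self.findings.append(ValidationFinding(kind, row, column, message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def __len__(self) -> int:
        return len(self.findings)

    def to_jsonl(self) -> str:
        import json
        return "\n".join(json.dumps(f.to_dict()) for f in self.findings)


def validate_records(df: pd.DataFrame, labelled: bool = False) -> ValidationReport:
    """Quality-control report: missing mandatory fields, duplicate
    (dataset, site, image) keys, out-of-range coordinates, unparseable
    datetimes.  Report-only; never mutates the input.
    """
    rep = ValidationReport()
    required = LABELLED_COLUMNS if labelled else UNLABELLED_COLUMNS
    for col in required:
        if col not in df.columns:
            rep.add("missing_column", None, col, f"column {col!r} absent")
    for col in ["url", "source", "dataset", "site", "image"]:
        if col not in df.columns:
            continue
        empty = df.index[df[col].astype(str) == ""]
        for row in empty:
            rep.add("missing_value", int(row), col, f"empty {col}")
    if all(c in df.columns for c in KEY_COLUMNS):
        dup = df.duplicated(subset=KEY_COLUMNS, keep="first")
        for row in df.index[dup]:
            rep.add("duplicate_key", int(row), None,
                    "duplicate (dataset, site, image) key")
    for col, lo, hi in [("latitude", -90, 90), ("longitude", -180, 180),
                        ("annotation_column", 0, 1), ("annotation_row", 0, 1)]:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col].mask(df[col].astype(str) == ""),
                               errors="coerce")
        bad = df.index[(vals < lo) | (vals > hi)]
        for row in bad:
            rep.add("out_of_range", int(row), col,
                    f"{col}={df[col].iloc[row]} outside [{lo}, {hi}]")
    if "datetime" in df.columns:
        raw = df["datetime"].astype(str)
        nonempty = raw != ""
        parsed = pd.to_datetime(raw[nonempty], format=DATETIME_FORMAT,
                                errors="coerce")
        for row in parsed.index[parsed.isna()]:
            rep.add("bad_datetime", int(row), "datetime",
                    f"datetime {raw[row]!r} does not match "
                    f"'YYYY-MM-DD HH:mm:ss'")
    if labelled:
        have_any = pd.Series(False, index=df.index)
        for col in CATAMI_COLUMNS + ["original_label"]:
            if col in df.columns:
                have_any |= df[col].astype(str) != ""
        for row in df.index[~have_any]:
            rep.add("missing_label", int(row), None,
                    "no CATAMI label and no original label")
        if ("annotation_column" in df.columns
                and "annotation_row" in df.columns):
            c = df["annotation_column"].astype(str) != ""
            r = df["annotation_row"].astype(str) != ""
            for row in df.index[c ^ r]:
                rep.add("half_point", int(row), None,
                        "annotation_row/column must be present together")
    return rep


def impute_coordinates(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing coordinates with the site's geographic mean centre.

    Records missing latitude/longitude within a (dataset, site) group that
    has at least one located image receive the arithmetic mean centre of the
    located images.  Returns ``(table, flags)`` where ``flags`` has boolean
    ``imputed`` and ``unlocatable`` columns aligned with the table.
    Idempotent: imputed values are themselves site means, so a second pass
    changes nothing.
    """
    out = df.copy()
    imputed = pd.Series(False, index=df.index)
    unlocatable = pd.Series(False, index=df.index)
    lat = pd.to_numeric(out["latitude"], errors="coerce")
    lon = pd.to_numeric(out["longitude"], errors="coerce")
    missing = lat.isna() | lon.isna()
    for _, idx in out.groupby(["dataset", "site"], sort=False).groups.items():
        idx = pd.Index(idx)
        m = missing[idx]
        if not m.any():
            continue
        located = idx[~m]
        if len(located) == 0:
            unlocatable[idx] = True
            continue
        clat, clon = geo.mean_centre(lat[located].to_numpy(),
                                     lon[located].to_numpy())
        fill = idx[m]
        out.loc[fill, "latitude"] = clat
        out.loc[fill, "longitude"] = clon
        imputed[fill] = True
    out["latitude"] = pd.to_numeric(out["latitude"], errors="coerce")
    out["longitude"] = pd.to_numeric(out["longitude"], errors="coerce")
    flags = pd.DataFrame({"imputed": imputed, "unlocatable": unlocatable})
    return out, flags


_DT_RE = re.compile(
    r"(?P<year>\d{4})"
    r"(?:[-/\.](?P<month>\d{1,2})"
    r"(?:[-/\.](?P<day>\d{1,2})"
    r"(?:[T ](?P<hour>\d{1,2}):(?P<minute>\d{2})"
    r"(?::(?P<second>\d{2})(?:\.\d+)?)?"
    r"(?P<tz>Z|[+-]\d{2}:?\d{2})?"
    r")?)?)?"
)

_PRECISIONS = ["year", "month", "day", "hour", "minute", "second"]


def standardize_datetime(raw: str, tz_hint: str | None = None) -> tuple[str, str]:
    """Normalize a partial datetime string to ``YYYY-MM-DD HH:mm:ss`` UTC.

    Missing month/day are imputed as 01 and missing time as 00:00:00; the
    returned precision tag records the finest component actually present
    (so downstream users know a ``1965-01-01 00:00:00`` may be accurate only
    to the year).  Timezone-aware inputs (trailing ``Z`` or ``+HH:MM``
    offset, or an explicit ``tz_hint`` offset like ``"+02:00"``) are
    converted to UTC; timezone-less inputs are assumed already UTC.

    Raises ValueError when no 4-digit year can be extracted.
    """
    raw = str(raw).strip()
    m = _DT_RE.search(raw)
    if not m:
        raise ValueError(f"no extractable year in {raw!r}")
    parts = m.groupdict()
    precision = "year"
    for p in _PRECISIONS:
        if p in parts and parts.get(p) is not None:
            precision = p
    vals = {p: int(parts[p]) if parts.get(p) else None for p in _PRECISIONS}
    dt = datetime(vals["year"], vals["month"] or 1, vals["day"] or 1,
                  vals["hour"] or 0, vals["minute"] or 0, vals["second"] or 0)
    tz = parts.get("tz") or tz_hint
    if tz and tz != "Z":
        sign = 1 if tz[0] == "+" else -1
        hh, mm = int(tz[1:3]), int(tz.replace(":", "")[3:5] or 0)
        dt = dt.replace(tzinfo=timezone(sign * timedelta(hours=hh, minutes=mm)))
        dt = dt.astimezone(timezone.utc).replace(tzinfo=None)
    return dt.strftime(DATETIME_FORMAT), precision


#: resized images target this shortest-side length in pixels
RESIZE_TARGET_PX = 512
#: images whose shortest side is within this tolerance of the target are kept
RESIZE_TOLERANCE = 0.10


def resize_dims(width: int, height: int) -> tuple[int, int]:
    """Dimensions after the shortest-side-to-512-px downscale rule.

    Images whose shortest side is already at most ``512 * 1.1`` pixels are
    left unchanged (never upscale); larger images are scaled so the shortest
    side is exactly 512, the other side scaled by the same factor and
    rounded to the nearest integer.
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    shortest = min(width, height)
    if shortest <= RESIZE_TARGET_PX * (1 + RESIZE_TOLERANCE):
        return width, height
    scale = RESIZE_TARGET_PX / shortest
    return (int(round(width * scale)), int(round(height * scale)))
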