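"""Readers and writers for digitized eye profiles, pixel patches and tables.

Formats
-------
Eye profile CSV
    Columns ``row,x,y,is_apex``.  ``row`` is 1-based and purely cosmetic
    (rows are read in file order); ``x,y`` are coordinates in the
    digitization's units; ``is_apex`` is 0/1 and at most one row may carry 1.
    When no apex flag is set the midpoint index is used.  Coordinates are
    written with 6 decimals, which round-trips the stated precision exactly.
Eye profile JSON
    Object with ``points`` (list of ``[x, y]``), ``apex_index`` (0-based),
    optional ``scale_mm_per_unit``, ``facet_rows_per_step``, ``specimen_id``.
Pixel patch
    Either a PNG (read through Pillow, RGB or grayscale) or a CSV holding a
    gray-value grid (``H`` rows x ``W`` columns, values 0-255).
Worker table CSV
    One row per specimen with the :class:`~ommatidics.model.WorkerRecord`
    scalar fields; regional facet diameters appear as ``regional_<region>``
    columns; an absent ocellus is encoded as the string ``ABSENT``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd
from PIL import Image

from .model import (
    ABSENT,
    EYE_REGIONS,
    EyeProfile,
    PixelPatch,
    ValidationError,
    WorkerRecord,
)

__all__ = [
    "read_eye_profile",
    "write_eye_profile",
    "read_patch",
    "read_worker_table",
    "write_worker_table",
]


def read_eye_profile(path, format: str | None = None, **kwargs) -> EyeProfile:
    """Read a digitized eye profile from CSV or JSON.

    ``format`` defaults to the file suffix.  Keyword arguments override
    metadata not present in the file (``scale_mm_per_unit``,
    ``facet_rows_per_step``, ``specimen_id``).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"could not parse {path}: {exc}") from exc
        if not {"x", "y"} <= set(df.columns):
            raise ValidationError("profile CSV needs columns x and y")
        try:
            pts = df[["x", "y"]].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric coordinates in {path}") from exc
        if "is_apex" in df.columns:
            flags = np.flatnonzero(df["is_apex"].fillna(0).astype(int).to_numpy())
            if len(flags) > 1:
                raise ValidationError("more than one apex flag set")
            apex = int(flags[0]) if len(flags) else len(pts) // 2
        else:
            apex = len(pts) // 2
        meta = {}
    elif fmt == "json":
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"could not parse {path}: {exc}") from exc
        try:
            pts = np.asarray(obj["points"], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric coordinates in {path}") from exc
        apex = int(obj.get("apex_index", len(pts) // 2))
        meta = {
            k: obj[k]
            for k in ("scale_mm_per_unit", "facet_rows_per_step", "specimen_id")
            if k in obj
        }
    else:
        raise ValidationError(f"unknown profile format {fmt!r}")
    meta.update(kwargs)
    return EyeProfile(points=pts, apex_index=apex, **meta)


def write_eye_profile(profile: EyeProfile, path, format: str | None = None) -> None:
    """Write a profile to CSV (6-decimal coordinates) or JSON.

    Coordinates are written in mm (scale already applied on read), so the
    written file carries ``scale_mm_per_unit`` 1.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.DataFrame(
            {
                "row": np.arange(1, len(profile) + 1),
                "x": profile.points[:, 0],
                "y": profile.points[:, 1],
                "is_apex": (np.arange(len(profile)) == profile.apex_index).astype(int),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "json":
        obj = {
            "points": [[round(x, 6), round(y, 6)] for x, y in profile.points],
            "apex_index": profile.apex_index,
            "scale_mm_per_unit": 1.0,
            "facet_rows_per_step": profile.facet_rows_per_step,
            "specimen_id": profile.specimen_id,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    else:
        raise ValidationError(f"unknown profile format {fmt!r}")


def read_patch(path) -> PixelPatch:
    """Read a pixel patch from PNG (RGB/gray) or CSV (gray grid)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        with Image.open(path) as img:
            if img.mode not in ("RGB", "L"):
                img = img.convert("RGB")
            arr = np.asarray(img, dtype=float)
        return PixelPatch(arr)
    try:
        arr = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"non-numeric patch values in {path}") from exc
    return PixelPatch(arr)


_SCALARS = [
    "species_id",
    "colony_id",
    "mesosoma_length",
    "eye_area",
    "facet_count",
    "facet_diameter_D",
    "ocellus_diameter",
    "dphi_deg",
    "span_deg",
]


def read_worker_table(path) -> List[WorkerRecord]:
    """Read a worker morphometry CSV into validated records."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        oc = row.get("ocellus_diameter")
        if isinstance(oc, str) and oc.strip().upper() == "ABSENT":
            oc = ABSENT
        elif pd.isna(oc):
            oc = None
        else:
            oc = float(oc)
        regional = {
            r: float(row[f"regional_{r}"])
            for r in EYE_REGIONS
            if f"regional_{r}" in df.columns and pd.notna(row[f"regional_{r}"])
        }
        records.append(
            WorkerRecord(
                species_id=str(row["species_id"]),
                colony_id=str(row.get("colony_id", "")),
                mesosoma_length=float(row["mesosoma_length"]),
                eye_area=float(row["eye_area"]),
                facet_count=int(row["facet_count"]),
                facet_diameter_D=float(row["facet_diameter_D"]),
                ocellus_diameter=oc,
                dphi_deg=None if pd.isna(row.get("dphi_deg")) else float(row["dphi_deg"]),
                span_deg=None if pd.isna(row.get("span_deg")) else float(row["span_deg"]),
                regional_D=regional,
            )
        )
    return records


def write_worker_table(records: Iterable[WorkerRecord], path) -> None:
    rows = []
    for rec in records:
        oc = rec.ocellus_diameter
        row = {
            "species_id": rec.species_id,
            "colony_id": rec.colony_id,
            "mesosoma_length": rec.mesosoma_length,
            "eye_area": rec.eye_area,
            "facet_count": rec.facet_count,
            "facet_diameter_D": rec.facet_diameter_D,
            "ocellus_diameter": "ABSENT" if oc is ABSENT else oc,
            "dphi_deg": rec.dphi_deg,
            "span_deg": rec.span_deg,
        }
        for r in EYE_REGIONS:
            if r in rec.regional_D:
                row[f"regional_{r}"] = rec.regional_D[r]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
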