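"""File formats: landmark JSON/CSV and the cohort CSV table.

Landmark JSON::

    {"view": "coronal", "points": {"knee_center": [0.0, 0.0], ...}}

Landmark CSV: columns ``view,name,x_mm,y_mm`` (one view per file).

Cohort CSV: one row per knee.  Columns: ``id, arm, age, bmi, sex,
planned_correction_deg, achieved_correction_deg, y1_mm, y2_mm`` followed by
``{pre,post}_{measure}_{true,measured}`` for the five deformity measures
(wbl_percent, mpta, mldfa, jlca, pts).  Values are written with full float
precision, so write -> read is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import pandas as pd

from .cohort import KneeRecord
from .errors import DataError, SchemaError
from .geometry import DeformityMeasures, LandmarkSet

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
]

_MEASURES = ("wbl_percent", "mpta", "mldfa", "jlca", "pts")
_META = (
    "id",
    "arm",
    "age",
    "bmi",
    "sex",
    "planned_correction_deg",
    "achieved_correction_deg",
    "y1_mm",
    "y2_mm",
)


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark set from JSON or CSV (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed landmark JSON: {exc}") from exc
        if not isinstance(payload, dict) or "view" not in payload or "points" not in payload:
            raise SchemaError("landmark JSON needs 'view' and 'points' keys")
        points = {}
        for name, xy in payload["points"].items():
            try:
                x, y = float(xy[0]), float(xy[1])
            except (TypeError, ValueError, IndexError) as exc:
                raise SchemaError(f"bad coordinate for landmark {name!r}") from exc
            points[name] = (x, y)
        return LandmarkSet(payload["view"], points)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"unreadable landmark CSV: {exc}") from exc
    needed = {"view", "name", "x_mm", "y_mm"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"landmark CSV needs columns {sorted(needed)}")
    views = set(df["view"])
    if len(views) != 1:
        raise SchemaError("landmark CSV must contain exactly one view")
    pts = {}
    for rec in df.itertuples(index=False):
        x, y = float(rec.x_mm), float(rec.y_mm)
        pts[str(rec.name)] = (x, y)
    return LandmarkSet(views.pop(), pts)


def write_landmarks(lms: LandmarkSet, path) -> None:
    """Write a landmark set as JSON or CSV (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"view": lms.view, "points": {k: list(v) for k, v in lms.points.items()}}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    rows = [
        {"view": lms.view, "name": k, "x_mm": v[0], "y_mm": v[1]}
        for k, v in lms.points.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_to_frame(records: List[KneeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {k: getattr(r, k) for k in _META}
        for phase, true, meas in (
            ("pre", r.true_pre, r.meas_pre),
            ("post", r.true_post, r.meas_post),
        ):
            for m in _MEASURES:
                row[f"{phase}_{m}_true"] = getattr(true, m) if true else float("nan")
                row[f"{phase}_{m}_measured"] = getattr(meas, m) if meas else float("nan")
        rows.append(row)
    cols = list(_META) + [
        f"{p}_{m}_{k}" for p in ("pre", "post") for m in _MEASURES for k in ("true", "measured")
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(df: pd.DataFrame) -> List[KneeRecord]:
    missing = [c for c in _META if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    records = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        def measures(phase: str, kind: str):
            try:
                vals = {m: float(rec[f"{phase}_{m}_{kind}"]) for m in _MEASURES}
            except (KeyError, TypeError, ValueError):
                return None
            if any(pd.isna(v) for v in vals.values()):
                return None
            return DeformityMeasures(**vals)

        records.append(
            KneeRecord(
                id=str(rec["id"]),
                arm=str(rec["arm"]),
                index=i,
                age=float(rec["age"]),
                bmi=float(rec["bmi"]),
                sex=str(rec["sex"]),
                true_pre=measures("pre", "true"),
                true_post=measures("post", "true"),
                meas_pre=measures("pre", "measured"),
                meas_post=measures("post", "measured"),
                planned_correction_deg=float(rec["planned_correction_deg"]),
                achieved_correction_deg=float(rec["achieved_correction_deg"]),
                y1_mm=float(rec["y1_mm"]),
                y2_mm=float(rec["y2_mm"]),
            )
        )
    return records


def write_cohort(records: List[KneeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort(path) -> List[KneeRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise DataError(f"unreadable cohort CSV: {exc}") from exc
    return frame_to_records(df)
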