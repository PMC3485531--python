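"""Readers and writers for the study, report and cohort file formats.

Study CSV (wide format, one study per file): a ``time_pct_rr`` column
followed by the 16 segment columns in canonical order (see
:data:`dyssync.curves.SEGMENT_NAMES`); an optional trailing ``global``
column is ignored on read and recomputed.  Study JSON:
``{"study_id": ..., "rr_interval_ms": ..., "times": [...],
"segments": {name: [...]}}``.

Reports serialize to JSON (all fields, per-segment entries) and to a flat
one-row-per-study CSV for cohort assembly.  The cohort CSV carries one row
per patient with all baseline and follow-up metrics, Δ-ESV and the
responder flag.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, records_to_frame
from .curves import GLOBAL_LABEL, SEGMENT_NAMES, SegmentalCurveSet, TimeVolumeCurve, global_curve
from .errors import ValidationError
from .metrics import DyssynchronyReport

TIME_COLUMN = "time_pct_rr"


def sha256_of(path: str | Path) -> str:
    """Hex digest of a file, for run provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# study formats


def _build_curve_set(
    times: np.ndarray,
    segments: dict[str, np.ndarray],
    study_id: str,
    rr_interval_ms: float | None = None,
    source: str = "",
) -> SegmentalCurveSet:
    times = np.asarray(times, dtype=float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        # +2: header line plus 1-based indexing of the second row of the pair
        raise ValidationError(
            f"{source}: time not strictly increasing at data line(s) "
            + ", ".join(str(i + 2) for i in bad[:5])
        )
    curves = {}
    for name, vol in segments.items():
        vol = np.asarray(vol, dtype=float)
        neg = np.flatnonzero(vol < 0)
        if neg.size:
            raise ValidationError(
                f"{source}: negative volume in segment {name!r} at data line(s) "
                + ", ".join(str(i + 2) for i in neg[:5])
            )
        curves[name] = TimeVolumeCurve(times, vol, name)
    return SegmentalCurveSet(curves, study_id=study_id, rr_interval_ms=rr_interval_ms)


def read_study_csv(path: str | Path) -> SegmentalCurveSet:
    """Read one study from the wide CSV format."""
    path = Path(path)
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise ValidationError(f"{path}: missing required column {TIME_COLUMN!r}")
    missing = [n for n in SEGMENT_NAMES if n not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing segment column(s): {', '.join(missing)}"
        )
    extra = [
        c for c in df.columns
        if c not in (TIME_COLUMN, GLOBAL_LABEL) and c not in SEGMENT_NAMES
    ]
    if extra:
        raise ValidationError(f"{path}: unknown column(s): {', '.join(extra)}")
    return _build_curve_set(
        df[TIME_COLUMN].to_numpy(),
        {n: df[n].to_numpy() for n in SEGMENT_NAMES},
        study_id=path.stem,
        source=str(path),
    )


def write_study_csv(curve_set: SegmentalCurveSet, path: str | Path) -> None:
    """Write one study to the wide CSV format (with a recomputed trailing
    ``global`` column for convenience; it is ignored on read)."""
    data = {TIME_COLUMN: curve_set.times}
    for n in SEGMENT_NAMES:
        data[n] = curve_set.segments[n].volumes
    data[GLOBAL_LABEL] = global_curve(curve_set).volumes
    pd.DataFrame(data).to_csv(path, index=False)


def read_study_json(path: str | Path) -> SegmentalCurveSet:
    """Read one study from the JSON format."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("times", "segments"):
        if key not in doc:
            raise ValidationError(f"{path}: missing key {key!r}")
    missing = [n for n in SEGMENT_NAMES if n not in doc["segments"]]
    if missing:
        raise ValidationError(f"{path}: missing segment(s): {', '.join(missing)}")
    return _build_curve_set(
        np.asarray(doc["times"], dtype=float),
        {n: np.asarray(doc["segments"][n], dtype=float) for n in SEGMENT_NAMES},
        study_id=str(doc.get("study_id", path.stem)),
        rr_interval_ms=doc.get("rr_interval_ms"),
        source=str(path),
    )


def write_study_json(curve_set: SegmentalCurveSet, path: str | Path) -> None:
    doc = {
        "study_id": curve_set.study_id,
        "rr_interval_ms": curve_set.rr_interval_ms,
        "times": curve_set.times.tolist(),
        "segments": {n: curve_set.segments[n].volumes.tolist() for n in SEGMENT_NAMES},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_study(path: str | Path) -> SegmentalCurveSet:
    """Dispatch on file extension (.csv / .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_study_json(path)
    if path.suffix.lower() == ".csv":
        return read_study_csv(path)
    raise ValidationError(f"{path}: unsupported study format {path.suffix!r}")


# ---------------------------------------------------------------------------
# reports


def write_report_json(report: DyssynchronyReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def reports_to_frame(reports: Sequence[DyssynchronyReport]) -> pd.DataFrame:
    """Flat one-row-per-study table of the scalar report fields."""
    rows = []
    for r in reports:
        rows.append(
            {
                "study_id": r.study_id,
                "edv_ml": r.edv,
                "esv_ml": r.esv,
                "ef_pct": r.ef,
                "sdi_pct_rr": r.sdi,
                "le_pct_rr": r.le,
                "pre_stv_ml_pct_rr": r.pre_stv,
                "post_stv_ml_pct_rr": r.post_stv,
                "total_stv_ml_pct_rr": r.total_stv,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort table


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read the flat per-patient cohort table (as written by
    :func:`write_cohort_csv`)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["patient_id", "responder", "delta_esv_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {', '.join(missing)}")
    return df
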