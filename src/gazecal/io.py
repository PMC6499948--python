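"""Frame-record schema and CSV round-tripping.

One row per camera frame, the adapter boundary of the whole pipeline: real
gaze-predictor output can be ingested through this schema just as the
synthetic generator writes it.

Columns
-------
subject_id : str
task_id    : str            one of grid / face_small / face_large / circle
frame_index: int            unique, non-negative within (subject, task)
waypoint_id: str            label of the scheduled true waypoint
true_x_cm, true_y_cm : float   scheduled gaze target (top-left frame, cm)
pred_x_cm, pred_y_cm : float   predicted gaze point; empty unless status=valid
status     : str            valid / blink / segmentation_failed / excluded_manual

Predictions are present if and only if ``status == "valid"``.  Files are
UTF-8 CSV with a header row, "." decimal separator, and missing predictions
encoded as empty fields; coordinates survive a write/read round trip at full
float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

FRAME_COLUMNS = [
    "subject_id",
    "task_id",
    "frame_index",
    "waypoint_id",
    "true_x_cm",
    "true_y_cm",
    "pred_x_cm",
    "pred_y_cm",
    "status",
]

STATUSES = ("valid", "blink", "segmentation_failed", "excluded_manual")


class FrameSchemaError(ValueError):
    """A frame table violates the schema; the message names offending lines."""


def validate_frames(frames: pd.DataFrame) -> pd.DataFrame:
    """Check the frame-table contract; returns the table unchanged.

    Line numbers in error messages count the CSV header as line 1, so the
    first data row is line 2.
    """
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise FrameSchemaError(f"missing columns: {', '.join(missing)}")

    bad_status = ~frames["status"].isin(STATUSES)
    if bad_status.any():
        lines = [str(i + 2) for i in np.flatnonzero(bad_status.to_numpy())[:5]]
        raise FrameSchemaError(f"unknown status on line(s) {', '.join(lines)}")

    valid = frames["status"] == "valid"
    pred_missing = frames["pred_x_cm"].isna() | frames["pred_y_cm"].isna()
    offenders = valid & pred_missing
    if offenders.any():
        lines = [str(i + 2) for i in np.flatnonzero(offenders.to_numpy())[:5]]
        raise FrameSchemaError(
            f"status=valid rows with missing prediction on line(s) {', '.join(lines)}"
        )
    offenders = ~valid & ~pred_missing
    if offenders.any():
        lines = [str(i + 2) for i in np.flatnonzero(offenders.to_numpy())[:5]]
        raise FrameSchemaError(
            f"non-valid rows carrying a prediction on line(s) {', '.join(lines)}"
        )

    if (frames["frame_index"] < 0).any():
        raise FrameSchemaError("negative frame_index")
    dup = frames.duplicated(subset=["subject_id", "task_id", "frame_index"])
    if dup.any():
        lines = [str(i + 2) for i in np.flatnonzero(dup.to_numpy())[:5]]
        raise FrameSchemaError(f"duplicate frame_index on line(s) {', '.join(lines)}")

    for col in ("true_x_cm", "true_y_cm"):
        if not np.isfinite(frames[col].to_numpy(dtype=float)).all():
            raise FrameSchemaError(f"non-finite values in {col}")
    return frames


def write_frames(frames: pd.DataFrame, path: str | Path) -> None:
    """Write frame records as UTF-8 CSV with full-precision floats."""
    validate_frames(frames)
    out = frames.loc[:, FRAME_COLUMNS]
    out.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_frames(path: str | Path) -> pd.DataFrame:
    """Read and validate a frame-record CSV.

    Malformed rows (non-numeric coordinates on valid rows, missing columns,
    schema violations) raise :class:`FrameSchemaError` naming the line.
    """
    try:
        frames = pd.read_csv(
            path,
            dtype={
                "subject_id": str,
                "task_id": str,
                "waypoint_id": str,
                "status": str,
            },
            encoding="utf-8",
        )
    except ValueError as exc:
        raise FrameSchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise FrameSchemaError(f"{path}: missing columns: {', '.join(missing)}")
    for col in ("true_x_cm", "true_y_cm", "pred_x_cm", "pred_y_cm"):
        coerced = pd.to_numeric(frames[col], errors="coerce")
        bad = coerced.isna() & frames[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FrameSchemaError(f"{path}: non-numeric {col} on line {line}")
        frames[col] = coerced
    frames["frame_index"] = frames["frame_index"].astype(int)
    return validate_frames(frames)
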