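"""Task error metrics: nearest-feature misclassification and circle-trace error.

Face tasks are scored by assigning each valid frame's predicted gaze point to
the nearest facial landmark (Euclidean distance to left eye, right eye, or
mouth) and reporting the per-subject proportion of wrongly assigned frames.
Under the default ``eyes_vs_mouth`` grouping the two eyes collapse into a
single class before comparison, since the endpoint of interest is whether
gaze toward the eye region can be separated from gaze toward the mouth; the
``three_way`` grouping scores all three landmarks separately for sensitivity
analysis.  Nearest-landmark ties break by the fixed order left_eye,
right_eye, mouth — a measure-zero event under continuous noise, pinned down
for determinism.

The circle task is scored as the per-subject mean Euclidean distance of the
predictions from the target, in two variants: ``to_outline`` measures the
distance to the nearest point of the circle itself, |dist(pred, centre) - r|,
and is the headline number; ``to_waypoint`` measures the distance to the
scheduled waypoint and is never smaller frame-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazecal.geometry import TaskSpec

#: fixed tie-break order for nearest-landmark assignment
LANDMARK_ORDER = ("left_eye", "right_eye", "mouth")

EYE_CLASS = {"left_eye": "eyes", "right_eye": "eyes", "mouth": "mouth"}


@dataclass(frozen=True)
class CircleError:
    """Per-subject circle-trace error summary (cm)."""

    per_frame: np.ndarray
    mean: float
    variant: str


def _ordered_landmarks(landmarks: dict[str, tuple[float, float]]) -> list[str]:
    known = [l for l in LANDMARK_ORDER if l in landmarks]
    extra = [l for l in landmarks if l not in LANDMARK_ORDER]
    return known + sorted(extra)


def classify_fixation(
    point: tuple[float, float], landmarks: dict[str, tuple[float, float]]
) -> str:
    """Assign a gaze point to the nearest named landmark.

    Ties break by the fixed landmark order (left_eye, right_eye, mouth,
    then any extra names alphabetically).
    """
    if not landmarks:
        raise ValueError("landmark set must be non-empty")
    p = np.asarray(point, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("non-finite gaze point")
    names = _ordered_landmarks(landmarks)
    dists = [float(np.hypot(*(p - np.asarray(landmarks[n])))) for n in names]
    return names[int(np.argmin(dists))]  # argmin takes the first minimum: tie-break


def classify_frames(
    frames: pd.DataFrame, landmarks: dict[str, tuple[float, float]]
) -> pd.Series:
    """Vectorised nearest-landmark assignment for the valid frames of a table."""
    names = _ordered_landmarks(landmarks)
    pts = frames.loc[:, ["pred_x_cm", "pred_y_cm"]].to_numpy(dtype=float)
    centres = np.asarray([landmarks[n] for n in names], dtype=float)
    d2 = ((pts[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    out = pd.Series(np.asarray(names, dtype=object)[idx], index=frames.index)
    out[frames["status"] != "valid"] = None
    return out


def misclassification_rate(
    frames: pd.DataFrame,
    landmarks: dict[str, tuple[float, float]],
    grouping: str = "eyes_vs_mouth",
) -> pd.Series:
    """Per-subject proportion of valid frames assigned to the wrong feature.

    ``eyes_vs_mouth`` collapses left/right eye into one class before
    comparison; ``three_way`` requires the exact landmark.  Only frames with
    ``status == "valid"`` enter the denominator.  Raises on subjects with no
    valid frames.
    """
    if grouping not in ("eyes_vs_mouth", "three_way"):
        raise ValueError(f"unknown grouping {grouping!r}")
    valid = frames[frames["status"] == "valid"].copy()
    counts = frames.groupby("subject_id").size()
    empty = counts.index.difference(valid["subject_id"].unique())
    if len(empty) > 0:
        raise ValueError(f"no valid frames for subject(s): {', '.join(map(str, empty))}")
    assigned = classify_frames(valid, landmarks)
    truth = valid["waypoint_id"]
    if grouping == "eyes_vs_mouth":
        assigned = assigned.map(lambda l: EYE_CLASS.get(l, l))
        truth = truth.map(lambda l: EYE_CLASS.get(l, l))
    wrong = (assigned != truth).astype(float)
    return wrong.groupby(valid["subject_id"]).mean()


def circle_error(
    frames: pd.DataFrame, spec: TaskSpec, variant: str = "to_outline"
) -> pd.Series:
    """Per-subject mean Euclidean circle-trace error in cm.

    ``to_outline``: |dist(prediction, centre) - radius|, the distance to the
    nearest point on the circle.  ``to_waypoint``: distance to the scheduled
    true waypoint.  Means are over valid frames only.
    """
    if variant not in ("to_outline", "to_waypoint"):
        raise ValueError(f"unknown variant {variant!r}")
    if spec.task_id != "circle" or spec.circle_centre is None:
        raise ValueError("spec must be the circle task")
    if not spec.circle_radius or spec.circle_radius <= 0:
        raise ValueError("circle radius must be positive")
    valid = frames[frames["status"] == "valid"]
    pred = valid.loc[:, ["pred_x_cm", "pred_y_cm"]].to_numpy(dtype=float)
    if variant == "to_waypoint":
        true = valid.loc[:, ["true_x_cm", "true_y_cm"]].to_numpy(dtype=float)
        d = np.hypot(*(pred - true).T)
    else:
        centre = np.asarray(spec.circle_centre, dtype=float)
        d = np.abs(np.hypot(*(pred - centre).T) - spec.circle_radius)
    return pd.Series(d, index=valid.index).groupby(valid["subject_id"]).mean()


def frame_circle_error(
    points: np.ndarray, spec: TaskSpec, variant: str = "to_outline"
) -> CircleError:
    """Circle error for a bare point array (single subject)."""
    pts = np.asarray(points, dtype=float)
    if spec.circle_radius is None or spec.circle_radius <= 0:
        raise ValueError("circle radius must be positive")
    centre = np.asarray(spec.circle_centre, dtype=float)
    if variant == "to_outline":
        d = np.abs(np.hypot(*(pts - centre).T) - spec.circle_radius)
    elif variant == "to_waypoint":
        raise ValueError("to_waypoint needs scheduled waypoints; use circle_error")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return CircleError(per_frame=d, mean=float(d.mean()), variant=variant)
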