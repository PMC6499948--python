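"""Screen coordinate system and fixation-task layouts.

The study protocol shows four printed fixation patterns on a phone screen:

* ``grid`` — a 4 x 4 calibration grid of 16 points,
* ``face_small`` — a face whose eyes and mouth are 3.1 cm apart,
* ``face_large`` — the same face enlarged to a 4.3 cm eye–mouth distance,
* ``circle`` — 12 waypoints equally spaced on a circle.

The participant fixates each waypoint for 1 s while the front camera records
at 30 fps, so each waypoint contributes 30 frames to the schedule.  Face
tasks follow the visiting sequence mouth, left eye, mouth, right eye and
repeat it five times.

All geometry lives in a canonical top-left-origin frame: x grows rightward,
y grows downward, units are centimetres.  A camera-origin frame (the native
frame of camera-relative gaze predictors) is supported through a declared
camera position on the :class:`ScreenLayout`; conversion between the two
frames is a pure translation.

The eye–mouth distance of a face layout is defined as the Euclidean distance
from the mouth point to the midpoint of the two eye points; the eyes are
placed symmetrically about the vertical line through the mouth, so that
single scalar fully determines the vertical placement of the eyes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TASK_IDS = ("grid", "face_small", "face_large", "circle")

#: eye–mouth separation in cm for the two face tasks
FACE_SEPARATIONS = {"face_small": 3.1, "face_large": 4.3}

#: fixed visiting sequence for face tasks, one repetition
FACE_SEQUENCE = ("mouth", "left_eye", "mouth", "right_eye")


@dataclass(frozen=True)
class ScreenLayout:
    """Physical screen geometry in cm, top-left-origin by default.

    ``camera_position`` is the camera's location expressed in the top-left
    frame; it may lie outside the screen rectangle (phone cameras sit above
    the display).  ``landmarks`` holds named facial-feature points for face
    tasks, in the active convention.
    """

    width: float = 6.2
    height: float = 11.0
    origin_convention: str = "top-left-origin"
    camera_position: tuple[float, float] = (3.1, -0.8)
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("screen width and height must be positive")
        if self.origin_convention not in ("camera-origin", "top-left-origin"):
            raise ValueError(f"unknown origin convention {self.origin_convention!r}")
        if self.origin_convention == "top-left-origin":
            for name, (x, y) in self.landmarks.items():
                if not (0 <= x <= self.width and 0 <= y <= self.height):
                    raise ValueError(f"landmark {name!r} at ({x}, {y}) lies off-screen")

    def to_camera_frame(self, points: np.ndarray) -> np.ndarray:
        """Translate top-left-frame points into the camera-origin frame."""
        return np.asarray(points, dtype=float) - np.asarray(self.camera_position)

    def to_topleft_frame(self, points: np.ndarray) -> np.ndarray:
        """Translate camera-origin-frame points into the top-left frame."""
        return np.asarray(points, dtype=float) + np.asarray(self.camera_position)


@dataclass(frozen=True)
class TaskSpec:
    """One fixation task: ordered waypoints plus timing.

    ``waypoints`` is the within-repetition visiting sequence; entries are
    ``(x, y)`` in cm.  ``labels`` carries an optional landmark label per
    waypoint (face tasks) or a waypoint identifier (grid/circle).  The full
    schedule is the waypoint sequence repeated ``repetitions`` times, each
    waypoint held for ``dwell_per_waypoint`` seconds at ``frame_rate`` fps.
    """

    task_id: str
    waypoints: tuple[tuple[float, float], ...]
    labels: tuple[str, ...]
    dwell_per_waypoint: float = 1.0
    repetitions: int = 1
    frame_rate: float = 30.0
    screen: ScreenLayout = field(default_factory=ScreenLayout)
    circle_centre: tuple[float, float] | None = None
    circle_radius: float | None = None

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValueError(f"unknown task id {self.task_id!r}")
        if not self.waypoints:
            raise ValueError("waypoint list must be non-empty")
        if len(self.labels) != len(self.waypoints):
            raise ValueError("labels must match waypoints one-to-one")
        if self.dwell_per_waypoint <= 0:
            raise ValueError("dwell_per_waypoint must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def frames_per_waypoint(self) -> int:
        return int(round(self.dwell_per_waypoint * self.frame_rate))

    @property
    def n_frames(self) -> int:
        return len(self.waypoints) * self.repetitions * self.frames_per_waypoint

    def waypoint_array(self) -> np.ndarray:
        return np.asarray(self.waypoints, dtype=float)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "task_id": self.task_id,
            "waypoints": [list(w) for w in self.waypoints],
            "labels": list(self.labels),
            "dwell_per_waypoint": self.dwell_per_waypoint,
            "repetitions": self.repetitions,
            "frame_rate": self.frame_rate,
            "screen": {
                "width": self.screen.width,
                "height": self.screen.height,
                "origin_convention": self.screen.origin_convention,
                "camera_position": list(self.screen.camera_position),
                "landmarks": {k: list(v) for k, v in self.screen.landmarks.items()},
            },
        }
        if self.circle_centre is not None:
            d["circle_centre"] = list(self.circle_centre)
            d["circle_radius"] = self.circle_radius
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        sc = d["screen"]
        screen = ScreenLayout(
            width=sc["width"],
            height=sc["height"],
            origin_convention=sc["origin_convention"],
            camera_position=tuple(sc["camera_position"]),
            landmarks={k: tuple(v) for k, v in sc.get("landmarks", {}).items()},
        )
        return cls(
            task_id=d["task_id"],
            waypoints=tuple(tuple(w) for w in d["waypoints"]),
            labels=tuple(d["labels"]),
            dwell_per_waypoint=d["dwell_per_waypoint"],
            repetitions=d["repetitions"],
            frame_rate=d["frame_rate"],
            screen=screen,
            circle_centre=tuple(d["circle_centre"]) if "circle_centre" in d else None,
            circle_radius=d.get("circle_radius"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TaskSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _grid_layout(screen: ScreenLayout, margin_x: float, margin_y: float) -> tuple[tuple, tuple]:
    xs = np.linspace(margin_x, screen.width - margin_x, 4)
    ys = np.linspace(margin_y, screen.height - margin_y, 4)
    pts, labels = [], []
    for i, y in enumerate(ys):  # row-major visiting order
        for j, x in enumerate(xs):
            pts.append((float(x), float(y)))
            labels.append(f"g{i}{j}")
    return tuple(pts), tuple(labels)


def _face_layout(
    screen: ScreenLayout, separation: float, mouth: tuple[float, float], eye_gap: float
) -> tuple[tuple, tuple, dict]:
    if separation <= 0:
        raise ValueError("eye–mouth separation must be positive")
    if eye_gap < 0:
        raise ValueError("eye gap must be non-negative")
    mx, my = mouth
    # eyes symmetric about the vertical through the mouth; their midpoint sits
    # directly above the mouth at the configured separation
    eye_y = my - separation
    left = (mx - eye_gap / 2.0, eye_y)
    right = (mx + eye_gap / 2.0, eye_y)
    landmarks = {"left_eye": left, "right_eye": right, "mouth": (mx, my)}
    named = {**landmarks}
    pts = tuple(named[l] for l in FACE_SEQUENCE)
    return pts, FACE_SEQUENCE, landmarks


def _circle_layout(centre: tuple[float, float], radius: float, n: int = 12) -> tuple[tuple, tuple]:
    if radius <= 0:
        raise ValueError("circle radius must be positive")
    cx, cy = centre
    pts, labels = [], []
    for k in range(n):
        theta = -math.pi / 2 + 2 * math.pi * k / n  # start at the top, clockwise in screen coords
        pts.append((cx + radius * math.cos(theta), cy + radius * math.sin(theta)))
        labels.append(f"c{k:02d}")
    return tuple(pts), tuple(labels)


def make_task_layout(
    task_id: str,
    screen: ScreenLayout | None = None,
    *,
    grid_margin_x: float = 1.0,
    grid_margin_y: float = 1.6,
    face_mouth: tuple[float, float] = (3.1, 7.8),
    face_eye_gap_small: float = 2.0,
    face_eye_gap_large: float = 2.8,
    face_separation: float | None = None,
    circle_centre: tuple[float, float] = (3.1, 5.5),
    circle_radius: float = 2.5,
    dwell: float = 1.0,
    frame_rate: float = 30.0,
) -> TaskSpec:
    """Construct the :class:`TaskSpec` for one of the four study tasks.

    Defaults fit a 6.2 cm x 11.0 cm portrait screen.  Grid margins, circle
    centre/radius and the absolute face placement are free layout parameters;
    the eye–mouth separations of the two face tasks (3.1 cm and 4.3 cm) are
    protocol constants unless ``face_separation`` overrides them.

    Raises ``ValueError`` for unknown task ids, off-screen circle waypoints,
    or non-positive separations.
    """
    screen = screen or ScreenLayout()
    if task_id == "grid":
        pts, labels = _grid_layout(screen, grid_margin_x, grid_margin_y)
        return TaskSpec(task_id, pts, labels, dwell, 1, frame_rate, screen)
    if task_id in ("face_small", "face_large"):
        sep = face_separation if face_separation is not None else FACE_SEPARATIONS[task_id]
        gap = face_eye_gap_small if task_id == "face_small" else face_eye_gap_large
        pts, labels, landmarks = _face_layout(screen, sep, face_mouth, gap)
        face_screen = ScreenLayout(
            screen.width, screen.height, screen.origin_convention,
            screen.camera_position, landmarks,
        )
        return TaskSpec(task_id, pts, labels, dwell, 5, frame_rate, face_screen)
    if task_id == "circle":
        pts, labels = _circle_layout(circle_centre, circle_radius)
        for x, y in pts:
            if not (0 <= x <= screen.width and 0 <= y <= screen.height):
                raise ValueError(
                    f"circle waypoint ({x:.2f}, {y:.2f}) lies off the "
                    f"{screen.width} x {screen.height} cm screen"
                )
        return TaskSpec(
            task_id, pts, labels, dwell, 1, frame_rate, screen,
            circle_centre=circle_centre, circle_radius=circle_radius,
        )
    raise ValueError(f"unknown task id {task_id!r}")


def default_task_suite(screen: ScreenLayout | None = None, **kwargs) -> dict[str, TaskSpec]:
    """All four tasks with shared screen and layout parameters."""
    return {tid: make_task_layout(tid, screen, **kwargs) for tid in TASK_IDS}


def fixation_schedule(spec: TaskSpec) -> list[tuple[int, str]]:
    """Expand a task into its per-frame schedule.

    Returns ``(frame_index, waypoint_label)`` pairs; the schedule length is
    ``n_waypoints x repetitions x dwell x frame_rate`` and the waypoint order
    follows the task's visiting sequence.
    """
    fpw = spec.frames_per_waypoint
    out: list[tuple[int, str]] = []
    idx = 0
    for _ in range(spec.repetitions):
        for label in spec.labels:
            for _ in range(fpw):
                out.append((idx, label))
                idx += 1
    return out


def schedule_points(spec: TaskSpec) -> tuple[np.ndarray, list[str]]:
    """Per-frame true gaze points and waypoint labels as arrays."""
    sched = fixation_schedule(spec)
    by_label = dict(zip(spec.labels, spec.waypoints))
    pts = np.array([by_label[lab] for _, lab in sched], dtype=float)
    return pts, [lab for _, lab in sched]
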