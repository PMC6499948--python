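"""Per-subject gaze calibration: moment matching and an SVR comparator.

The linear method corrects each axis independently with an affine map

    x_tilde = a_x * x_hat + b_x,    a_x = sqrt(var_x(truth) / var_x(pred)),
                                    b_x = mean_x(truth) - a_x * mean_x(pred)

(y analogous), the unique positive-gain affine transform under which the
corrected predictions share the truth set's centroid and per-axis variance.
Variances use the population convention (divide by n); the variance ratio is
convention-invariant as long as both sides use the same one, and the offset
depends only on means, so the choice only pins down bit-level reproducibility.
Because the gain is a square root it is always positive: a mirror-image
corruption (negative gain) is outside the model and is not corrected.

The comparator is epsilon-insensitive support vector regression, one RBF
regressor per output axis, fitted on the same calibration-task data.  Real
CNN-based predictors expose internal feature vectors for this role; here the
feature vector is built from the predicted point itself, optionally extended
with its quadratic terms, which preserves the method's form (nonlinear
regression from prediction-derived features to truth) while keeping the
pipeline self-contained.

Both methods are fitted per subject on that subject's valid calibration-grid
frames only, then applied to the remaining tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR


class DegenerateCalibrationError(ValueError):
    """Prediction variance vanished on an axis; the gain is undefined.

    Raised instead of silently falling back to a translation-only fit, which
    would corrupt the method comparison.
    """


@dataclass(frozen=True)
class MomentSummary:
    """Per-axis mean (cm) and population variance (cm^2) of a point set."""

    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    n: int


@dataclass(frozen=True)
class LinearCalibration:
    """Fitted per-axis affine correction; gains dimensionless, offsets cm."""

    a_x: float
    a_y: float
    b_x: float
    b_y: float

    def __post_init__(self) -> None:
        if self.a_x <= 0 or self.a_y <= 0:
            raise ValueError("gains must be positive")

    def to_dict(self) -> dict:
        return {"a_x": self.a_x, "a_y": self.a_y, "b_x": self.b_x, "b_y": self.b_y}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearCalibration":
        return cls(d["a_x"], d["a_y"], d["b_x"], d["b_y"])


@dataclass
class SVRCalibration:
    """One fitted support-vector regressor per output axis."""

    model_x: Pipeline
    model_y: Pipeline
    hyperparameters: dict
    feature_set: str = "point"


def moments(points: np.ndarray) -> MomentSummary:
    """Per-axis mean and population variance of >= 2 finite 2-D points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    mu = pts.mean(axis=0)
    var = pts.var(axis=0)  # ddof=0, population convention
    return MomentSummary(mu[0], mu[1], var[0], var[1], len(pts))


def fit_linear(predictions: np.ndarray, truths: np.ndarray) -> LinearCalibration:
    """Fit the moment-matching affine correction on a calibration set.

    Raises :class:`DegenerateCalibrationError` if the predictions have zero
    variance on either axis (all collinear with an axis), where the gain
    a = sqrt(var_truth / var_pred) is undefined.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have equal shapes")
    mp, mt = moments(p), moments(t)
    if mp.var_x <= 0 or mp.var_y <= 0:
        raise DegenerateCalibrationError(
            f"zero prediction variance (var_x={mp.var_x}, var_y={mp.var_y})"
        )
    a_x = float(np.sqrt(mt.var_x / mp.var_x))
    a_y = float(np.sqrt(mt.var_y / mp.var_y))
    return LinearCalibration(
        a_x=a_x,
        a_y=a_y,
        b_x=mt.mu_x - a_x * mp.mu_x,
        b_y=mt.mu_y - a_y * mp.mu_y,
    )


def apply_linear(model: LinearCalibration, points: np.ndarray) -> np.ndarray:
    """Apply the per-axis affine correction elementwise."""
    pts = np.asarray(points, dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite input points")
    return pts * np.array([model.a_x, model.a_y]) + np.array([model.b_x, model.b_y])


def build_features(points: np.ndarray, feature_set: str = "point") -> np.ndarray:
    """Feature matrix for the SVR comparator.

    ``point``      -> (x_hat, y_hat)
    ``quadratic``  -> (x_hat, y_hat, x_hat^2, y_hat^2, x_hat*y_hat)
    """
    pts = np.asarray(points, dtype=float)
    if feature_set == "point":
        return pts
    if feature_set == "quadratic":
        x, y = pts[:, 0], pts[:, 1]
        return np.column_stack([x, y, x**2, y**2, x * y])
    raise ValueError(f"unknown feature set {feature_set!r}")


DEFAULT_SVR_PARAMS = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1, "gamma": "scale"}


def fit_svr(
    features: np.ndarray,
    truths: np.ndarray,
    hyperparameters: dict | None = None,
    feature_set: str = "point",
) -> SVRCalibration:
    """Fit one epsilon-SVR per output axis on the calibration data.

    Defaults: RBF kernel, C=1, epsilon=0.1, gamma scaled by feature variance
    after unit-variance standardisation — the reference conventions of the
    common SVR implementations.  Deterministic for fixed data and settings.
    """
    X = np.asarray(features, dtype=float)
    t = np.asarray(truths, dtype=float)
    if len(X) != len(t):
        raise ValueError("feature/target length mismatch")
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    params = {**DEFAULT_SVR_PARAMS, **(hyperparameters or {})}
    models = []
    for axis in (0, 1):
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(**params))]
        )
        pipe.fit(X, t[:, axis])
        models.append(pipe)
    return SVRCalibration(models[0], models[1], params, feature_set)


def apply_svr(model: SVRCalibration, features: np.ndarray) -> np.ndarray:
    """Predict corrected points from feature vectors with a fitted SVR pair."""
    X = np.asarray(features, dtype=float)
    return np.column_stack([model.model_x.predict(X), model.model_y.predict(X)])
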