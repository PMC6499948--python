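"""Nearest-feature misclassification and circle-trace error."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gazecal.geometry import make_task_layout
from gazecal.metrics import (
    classify_fixation,
    circle_error,
    frame_circle_error,
    misclassification_rate,
)

LANDMARKS = {"left_eye": (2.1, 4.7), "right_eye": (4.1, 4.7), "mouth": (3.1, 7.8)}


def frame_table(true_labels, pred_points, landmarks=LANDMARKS, subject="s1"):
    pts = np.asarray(pred_points, dtype=float)
    truth = np.asarray([landmarks[l] for l in true_labels], dtype=float)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "task_id": "face_small",
            "frame_index": np.arange(len(pts)),
            "waypoint_id": true_labels,
            "true_x_cm": truth[:, 0],
            "true_y_cm": truth[:, 1],
            "pred_x_cm": pts[:, 0],
            "pred_y_cm": pts[:, 1],
            "status": "valid",
        }
    )


class TestClassify:
    def test_point_at_landmark(self):
        assert classify_fixation(LANDMARKS["mouth"], LANDMARKS) == "mouth"

    def test_eye_midpoint_tie_breaks_to_left_eye(self):
        # exactly representable coordinates so the tie is exact in floats
        marks = {"left_eye": (2.0, 4.0), "right_eye": (4.0, 4.0), "mouth": (3.0, 8.0)}
        assert classify_fixation((3.0, 4.0), marks) == "left_eye"

    def test_agrees_with_brute_force_on_random_points(self, rng):
        pts = rng.uniform(-2, 12, size=(1000, 2))
        names = list(LANDMARKS)
        centres = np.array([LANDMARKS[n] for n in names])
        for p in pts:
            d = np.hypot(*(centres - p).T)
            expected = names[int(np.argmin(d))]
            # brute force scans in the same declared tie-break order
            assert classify_fixation(tuple(p), LANDMARKS) == expected

    def test_empty_landmarks_rejected(self):
        with pytest.raises(ValueError):
            classify_fixation((0.0, 0.0), {})


class TestMisclassification:
    def test_perfect_predictions_score_zero(self):
        labels = ["mouth", "left_eye", "mouth", "right_eye"] * 5
        pts = [LANDMARKS[l] for l in labels]
        rate = misclassification_rate(frame_table(labels, pts), LANDMARKS)
        assert rate.loc["s1"] == 0.0

    def test_all_predictions_at_mouth_half_wrong(self):
        labels = ["mouth", "left_eye"] * 10
        pts = [LANDMARKS["mouth"]] * 20
        rate = misclassification_rate(frame_table(labels, pts), LANDMARKS)
        assert rate.loc["s1"] == 0.5

    def test_eyes_vs_mouth_forgives_left_right_confusion(self):
        labels = ["left_eye"] * 10
        pts = [LANDMARKS["right_eye"]] * 10
        tbl = frame_table(labels, pts)
        assert misclassification_rate(tbl, LANDMARKS, "eyes_vs_mouth").loc["s1"] == 0.0
        assert misclassification_rate(tbl, LANDMARKS, "three_way").loc["s1"] == 1.0

    def test_invalid_frames_excluded_from_denominator(self):
        labels = ["mouth"] * 4
        pts = [LANDMARKS["mouth"], LANDMARKS["left_eye"],
               LANDMARKS["mouth"], LANDMARKS["mouth"]]
        tbl = frame_table(labels, pts)
        tbl.loc[1, "status"] = "blink"  # the only wrong frame is a blink
        tbl.loc[1, ["pred_x_cm", "pred_y_cm"]] = np.nan
        assert misclassification_rate(tbl, LANDMARKS).loc["s1"] == 0.0

    def test_no_valid_frames_errors(self):
        tbl = frame_table(["mouth"], [LANDMARKS["mouth"]])
        tbl["status"] = "blink"
        tbl[["pred_x_cm", "pred_y_cm"]] = np.nan
        with pytest.raises(ValueError):
            misclassification_rate(tbl, LANDMARKS)

    def test_rigid_motion_invariance(self, rng):
        labels = ["mouth", "left_eye"] * 50
        pts = np.array([LANDMARKS[l] for l in labels]) + rng.normal(0, 2, (100, 2))
        base = misclassification_rate(frame_table(labels, pts), LANDMARKS).loc["s1"]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([3.0, -2.0])
        moved_marks = {k: tuple(R @ np.asarray(v) + shift) for k, v in LANDMARKS.items()}
        moved_pts = pts @ R.T + shift
        moved = misclassification_rate(
            frame_table(labels, moved_pts, moved_marks), moved_marks
        ).loc["s1"]
        assert moved == base

    @pytest.mark.parametrize("d,sigma", [(3.1, 1.0), (3.1, 2.0), (4.3, 1.0), (4.3, 2.0)])
    def test_two_landmark_gaussian_matches_normal_cdf(self, d, sigma):
        """With two landmarks d apart and isotropic noise sigma, the midline
        is the decision boundary, so the error rate is Phi(-d/(2 sigma))."""
        rng = np.random.default_rng(int(d * 100 + sigma))
        marks = {"left_eye": (3.0, 2.0), "mouth": (3.0, 2.0 + d)}
        n = 10_000
        labels = ["left_eye"] * (n // 2) + ["mouth"] * (n // 2)
        pts = np.array([marks[l] for l in labels]) + rng.normal(0, sigma, (n, 2))
        rate = misclassification_rate(frame_table(labels, pts), marks).loc["s1"]
        p = norm.cdf(-d / (2 * sigma))
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_rate_decreases_with_separation(self):
        """Paired noise draws: the enlarged-face separation (4.3 cm) yields
        strictly fewer errors than the small face (3.1 cm) at equal noise."""
        rng = np.random.default_rng(42)
        n = 20_000
        noise = rng.normal(0, 2.0, (n, 2))
        rates = {}
        for d in (3.1, 4.3):
            marks = {"left_eye": (3.0, 2.0), "mouth": (3.0, 2.0 + d)}
            labels = ["left_eye"] * (n // 2) + ["mouth"] * (n // 2)
            pts = np.array([marks[l] for l in labels]) + noise
            rates[d] = misclassification_rate(frame_table(labels, pts), marks).loc["s1"]
        assert rates[4.3] < rates[3.1]


class TestCircle:
    spec = make_task_layout("circle", circle_centre=(3.1, 5.5), circle_radius=2.5)

    def circle_table(self, pred):
        from gazecal.geometry import schedule_points

        true, labels = schedule_points(self.spec)
        return pd.DataFrame(
            {
                "subject_id": "s1",
                "task_id": "circle",
                "frame_index": np.arange(len(true)),
                "waypoint_id": labels,
                "true_x_cm": true[:, 0],
                "true_y_cm": true[:, 1],
                "pred_x_cm": np.asarray(pred)[:, 0],
                "pred_y_cm": np.asarray(pred)[:, 1],
                "status": "valid",
            }
        )

    def test_perfect_trace_scores_zero_in_both_variants(self):
        from gazecal.geometry import schedule_points

        true, _ = schedule_points(self.spec)
        tbl = self.circle_table(true)
        assert circle_error(tbl, self.spec, "to_outline").loc["s1"] == pytest.approx(0, abs=1e-12)
        assert circle_error(tbl, self.spec, "to_waypoint").loc["s1"] == 0.0

    def test_prediction_at_centre_scores_radius(self):
        centre = np.tile([3.1, 5.5], (self.spec.n_frames, 1))
        tbl = self.circle_table(centre)
        assert circle_error(tbl, self.spec, "to_outline").loc["s1"] == pytest.approx(2.5)

    def test_wrong_waypoint_separates_variants(self):
        """A prediction on the circle but at the wrong waypoint: outline
        error 0, waypoint error > 0."""
        from gazecal.geometry import schedule_points

        true, _ = schedule_points(self.spec)
        rolled = np.roll(true, 30, axis=0)  # everyone fixates the previous waypoint
        tbl = self.circle_table(rolled)
        assert circle_error(tbl, self.spec, "to_outline").loc["s1"] == pytest.approx(0, abs=1e-12)
        assert circle_error(tbl, self.spec, "to_waypoint").loc["s1"] > 1.0

    def test_outline_error_bounded_by_waypoint_error(self, rng):
        pred = rng.uniform(0, 10, (self.spec.n_frames, 2))
        tbl = self.circle_table(pred)
        out = circle_error(tbl, self.spec, "to_outline").loc["s1"]
        way = circle_error(tbl, self.spec, "to_waypoint").loc["s1"]
        assert out <= way + 1e-12

    def test_outline_error_rotation_invariant_waypoint_error_not(self, rng):
        pred = rng.normal([3.1, 5.5], 1.5, (self.spec.n_frames, 2))
        centre = np.array([3.1, 5.5])
        theta = 2 * np.pi / 12  # rotate by one waypoint spacing
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rot = (pred - centre) @ R.T + centre
        t0, t1 = self.circle_table(pred), self.circle_table(rot)
        assert circle_error(t1, self.spec, "to_outline").loc["s1"] == pytest.approx(
            circle_error(t0, self.spec, "to_outline").loc["s1"], abs=1e-9
        )
        assert circle_error(t1, self.spec, "to_waypoint").loc["s1"] != pytest.approx(
            circle_error(t0, self.spec, "to_waypoint").loc["s1"], abs=1e-6
        )

    def test_frame_level_helper_and_bad_variant(self):
        res = frame_circle_error(np.array([[3.1, 5.5]]), self.spec)
        assert res.mean == pytest.approx(2.5)
        with pytest.raises(ValueError):
            circle_error(self.circle_table(np.zeros((360, 2))), self.spec, "nearest")
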