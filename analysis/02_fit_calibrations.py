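"""Fit both per-subject calibrations on the calibration-grid task.

The moment-matching linear transform has a closed form from the grid's
per-axis means and variances; the SVR comparator fits one RBF regressor per
output axis on the same frames.  Linear coefficients are written to
results/calibration_models.json.
"""

import argparse
import json
from pathlib import Path

from gazecal.calibration import build_features, fit_linear, fit_svr
from gazecal.io import read_frames

ap = argparse.ArgumentParser()
ap.add_argument("--frames", type=Path, default=Path("scratch/cohort/frames.csv"))
ap.add_argument("--out", type=Path, default=Path("results/calibration_models.json"))
args = ap.parse_args()

frames = read_frames(args.frames)
models = {}
for subject, sub in frames.groupby("subject_id"):
    grid = sub[(sub["task_id"] == "grid") & (sub["status"] == "valid")]
    pred = grid[["pred_x_cm", "pred_y_cm"]].to_numpy(float)
    true = grid[["true_x_cm", "true_y_cm"]].to_numpy(float)
    lin = fit_linear(pred, true)
    fit_svr(build_features(pred), true)  # fitted per subject at scoring time too
    models[subject] = lin.to_dict()

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(models, indent=2, sort_keys=True))

gains = [(m["a_x"], m["a_y"]) for m in models.values()]
offsets = [(m["b_x"], m["b_y"]) for m in models.values()]
print(f"fitted linear calibrations for {len(models)} subjects")
print(f"gain range  a_x: {min(g[0] for g in gains):.2f}..{max(g[0] for g in gains):.2f}, "
      f"a_y: {min(g[1] for g in gains):.2f}..{max(g[1] for g in gains):.2f}")
print(f"offset range b_x: {min(o[0] for o in offsets):+.2f}..{max(o[0] for o in offsets):+.2f} cm")
print(f"wrote {args.out}")
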