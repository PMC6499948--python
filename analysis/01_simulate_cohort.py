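"""Simulate the 16-subject synthetic study cohort.

Each subject performs the calibration grid, both face tasks and the circle
task with a subject-specific shift/gain corruption, frame-level jitter, and
blink/segmentation dropout.  Frames land in scratch/cohort/frames.csv (they
are bulky and fully regenerable from the seed).
"""

import argparse
from pathlib import Path

from gazecal.geometry import default_task_suite
from gazecal.io import write_frames
from gazecal.synth import CohortHyperparameters, simulate_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-subjects", type=int, default=16)
ap.add_argument("--out", type=Path, default=Path("scratch/cohort/frames.csv"))
args = ap.parse_args()

suite = default_task_suite()
frames = simulate_cohort(
    args.n_subjects, CohortHyperparameters(), list(suite.values()), args.seed
)
args.out.parent.mkdir(parents=True, exist_ok=True)
write_frames(frames, args.out)

valid = (frames["status"] == "valid").mean()
print(f"simulated {args.n_subjects} subjects x 4 tasks = {len(frames)} frames")
print(f"frame segmentation/blink survival: {100 * valid:.1f}% valid")
print(f"wrote {args.out}")
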