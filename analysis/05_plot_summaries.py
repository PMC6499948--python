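"""Optional figures: per-subject error by task and correction (box plots).

Requires matplotlib (the `plots` extra); writes PNGs to results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ap = argparse.ArgumentParser()
ap.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
ap.add_argument("--out-dir", type=Path, default=Path("results/figures"))
args = ap.parse_args()

metrics = pd.read_csv(args.metrics)
args.out_dir.mkdir(parents=True, exist_ok=True)

titles = {
    "face_small": "Small face: eye-vs-mouth misclassification",
    "face_large": "Enlarged face: eye-vs-mouth misclassification",
    "circle": "Circle trace: mean distance to outline (cm)",
}
for task_id, title in titles.items():
    piv = metrics[metrics["task_id"] == task_id].pivot(
        index="subject_id", columns="correction", values="value"
    )[["none", "svr", "linear"]]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.boxplot([piv[c].dropna() for c in piv.columns], tick_labels=piv.columns)
    ax.set_title(title, fontsize=10)
    ax.set_ylabel("error")
    fig.tight_layout()
    path = args.out_dir / f"{task_id}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    print(f"wrote {path}")
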