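"""Statistical comparison of the corrections.

For each task the three pairwise comparisons (none/linear, none/svr,
linear/svr) run through the Shapiro–Wilk-gated paired protocol; for the two
face tasks a Levene test compares pre-calibration inter-subject variance
against the pooled post-calibration sample.  Table: results/statistics.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from gazecal.pipeline import run_statistics

ap = argparse.ArgumentParser()
ap.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
ap.add_argument("--out", type=Path, default=Path("results/statistics.csv"))
args = ap.parse_args()

metrics = pd.read_csv(args.metrics)
stats = run_statistics(metrics)
args.out.parent.mkdir(parents=True, exist_ok=True)
stats.to_csv(args.out, index=False, float_format="%.17g")

for _, row in stats.iterrows():
    if row["test_used"] == "levene":
        print(f"{row['comparison']}: F = {row['F_statistic']:.2f}, "
              f"df = ({int(row['df1'])}, {int(row['df2'])}), p = {row['p_value']:.4g}")
    elif row["test_used"] == "degenerate":
        print(f"{row['comparison']}: degenerate ({row['reason']})")
    else:
        stat_name = "t" if row["test_used"] == "paired_t" else "V"
        print(f"{row['comparison']}: {row['test_used']} {stat_name} = "
              f"{row['statistic']:.4g}, p = {row['p_value']:.4g}")
print(f"wrote {args.out}")
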