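#!/usr/bin/env python
"""Group comparisons over the measured cell table.

Reads results/imaging/cells.csv (written by 01_imaging_populations.py),
reruns the planned Student's t-tests, the per-group random-effects ANOVA
over differentiation batches, and the helothermine rescue assessment, and
writes a tidy statistics table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cardiotransit.groupstats import compare_groups
from cardiotransit.pipeline import DEFAULT_COMPARISON_PLAN

parser = argparse.ArgumentParser()
parser.add_argument("--cells", type=Path, default=Path("results/imaging/cells.csv"))
parser.add_argument("--out", type=Path, default=Path("results/imaging"))
args = parser.parse_args()

cells = pd.read_csv(args.cells)
results, rescue_flags, table = compare_groups(cells, DEFAULT_COMPARISON_PLAN)

args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "stats.csv", index=False)
print(table.to_string(index=False))

for r in results:
    if not r.anova:
        continue
    for metric, a in r.anova.items():
        print(
            f"{r.group_label}/{metric}: sigma2_between={a.sigma2_between:.4g} "
            f"sigma2_within={a.sigma2_within:.4g} F={a.f_stat:.2f} p={a.p_value:.3g}"
        )
print(f"rescue flags: {rescue_flags}")
(args.out / "rescue_flags.json").write_text(json.dumps(rescue_flags, indent=1))
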