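"""Pairwise interobserver agreement over the simulated observer tables.

Reads observer_values.csv from 01_simulate.py and computes, for every
observer pair, measure (rest MBF, stress MBF, MFR), level and region:
the ICC, the mean difference as percent of the grand median, and the
dual-criterion verdict (ICC >= 0.75 and |diff| < 20% of median).

Run:  python analysis/03_agreement.py
"""

import argparse
from pathlib import Path

from mbfagree import io as mio
from mbfagree.agreement import compare_all, summarize_comparisons

ap = argparse.ArgumentParser()
ap.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

table = mio.read_observer_table(args.dir / "observer_values.csv")
comparisons = compare_all(table)
comparisons.to_csv(args.dir / "comparisons.csv", index=False)
summary = summarize_comparisons(comparisons, table)
mio.write_json(summary, args.dir / "summary.json")

print(f"{summary['n_comparisons']} comparisons, "
      f"{summary['n_failing']} outside the agreement criteria")
for measure, levels in summary["measures"].items():
    for level, st in levels.items():
        print(f"  {measure:>10s} {level:>9s}: median {st['median']:.2f}, "
              f"90% of |diffs| <= {st['q90_abs_pct_diff']:.1f}% of median, "
              f"min ICC {st['min_icc']:.3f}, "
              f"{st['n_failing']}/{st['n_comparisons']} failing")
print(f"wrote {args.dir / 'comparisons.csv'} and {args.dir / 'summary.json'}")
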