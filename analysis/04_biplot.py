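"""Draw the agreement biplots.

Reads comparisons.csv from 03_agreement.py and renders the
difference-vs-(1-ICC) biplot with the excellent-agreement rectangle:
one figure for the global/territory levels, one for the 17 segments.

Run:  python analysis/04_biplot.py
"""

import argparse
from pathlib import Path

import pandas as pd

from mbfagree.plots import make_biplot

ap = argparse.ArgumentParser()
ap.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

comparisons = pd.read_csv(args.dir / "comparisons.csv")
for name, levels in [("global_territory", ["global", "territory"]),
                     ("segment", ["segment"])]:
    sub = comparisons[comparisons["level"].isin(levels)]
    _, coords = make_biplot(
        sub, out_path=args.dir / f"biplot_{name}.svg",
        coords_path=args.dir / f"biplot_{name}.csv",
        title=f"Interobserver agreement ({name.replace('_', ' + ')})")
    inside = ((coords.x.abs() < 20) & (coords.y <= 0.25)).sum()
    print(f"{name}: {inside}/{len(coords)} points inside the "
          f"excellent-agreement rectangle; wrote biplot_{name}.svg")
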