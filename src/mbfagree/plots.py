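"""Agreement biplot: percent-of-median difference vs 1 - ICC.

Each pairwise comparison is one point; the origin is the point of
identity (no difference, ICC = 1).  The green rectangle
x in [-diff_max, +diff_max], y in [0, 1 - icc_min] encloses the region
of excellent agreement, so point-in-rectangle classification coincides
with the dual agreement verdict (x strict, y boundary-inclusive, mirroring
|diff| < 20% and ICC >= 0.75).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .agreement import AgreementCriteria, pairwise_comparisons

__all__ = ["biplot_coordinates", "make_biplot"]

_REGION_CODE = {"global": "g", "LAD": "LAD", "LCx": "LCx", "RCA": "RCA"}


def _point_label(region_id: str, ordinal: int) -> str:
    return f"{_REGION_CODE.get(region_id, region_id)}-{ordinal}"


def biplot_coordinates(results: pd.DataFrame) -> pd.DataFrame:
    """Plotted coordinates for each comparison.

    Returns columns ``label, x, y, parameter, condition, level,
    region_id, pair`` with x = pct_of_median and y = 1 - ICC; the label
    is the region code plus the ordinal (1..N(N-1)/2) of the observer
    pair in lexicographic order, e.g. ``s14-3``.
    """
    if results.empty:
        raise ValueError("no comparison results to plot")
    observers = sorted(set(results["observer_a"]) | set(results["observer_b"]))
    order = {f"{a}-{b}": i + 1
             for i, (a, b) in enumerate(pairwise_comparisons(observers))}
    out = results.copy()
    out["x"] = out["pct_of_median"]
    out["y"] = 1.0 - out["icc"]
    out["label"] = [_point_label(r, order[p])
                    for r, p in zip(out["region_id"], out["pair"])]
    return out[["label", "x", "y", "parameter", "condition", "level",
                "region_id", "pair"]].reset_index(drop=True)


def make_biplot(results: pd.DataFrame,
                criteria: AgreementCriteria = AgreementCriteria(),
                out_path=None,
                abs_x: bool = False,
                title: str | None = None,
                coords_path=None) -> tuple[plt.Figure, pd.DataFrame]:
    """Draw the agreement biplot; optionally write figure and coordinates.

    The rectangle's y-extent is 1 - icc_min (0.25 for the default 0.75
    threshold) and rescales with the criteria.  ``abs_x`` folds the
    signed percent differences to absolute values.
    """
    coords = biplot_coordinates(results)
    x = coords["x"].abs() if abs_x else coords["x"]
    y = coords["y"]

    fig, ax = plt.subplots(figsize=(7.0, 5.5))
    y_max = 1.0 - criteria.icc_min
    x_lo = 0.0 if abs_x else -criteria.diff_max_pct
    rect = plt.Rectangle((x_lo, 0.0),
                         criteria.diff_max_pct - x_lo, y_max,
                         facecolor="#c8e6c9", edgecolor="green", zorder=0,
                         label="excellent agreement")
    ax.add_patch(rect)
    markers = {"MBF/rest": ("o", "tab:blue"), "MBF/stress": ("s", "tab:red"),
               "MFR/ratio": ("^", "tab:purple")}
    for (param, cond), grp in coords.groupby(["parameter", "condition"]):
        m, c = markers.get(f"{param}/{cond}", ("o", "gray"))
        gx = grp["x"].abs() if abs_x else grp["x"]
        name = f"{cond} MBF" if param == "MBF" else "MFR"
        ax.scatter(gx, grp["y"], marker=m, s=22, color=c, alpha=0.75,
                   label=name, zorder=2)
    for _, row in coords.iterrows():
        px = abs(row["x"]) if abs_x else row["x"]
        if not (abs(row["x"]) < criteria.diff_max_pct
                and row["y"] <= y_max):
            ax.annotate(row["label"], (px, row["y"]), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.plot(0, 0, "k+", markersize=10, zorder=3)  # point of identity
    ax.axhline(0, color="0.7", lw=0.5)
    ax.axvline(0, color="0.7", lw=0.5)
    ax.set_xlabel("difference, % of median")
    ax.set_ylabel("1 − ICC")
    lim = max(criteria.diff_max_pct * 1.3,
              float(np.abs(x).max()) * 1.15 if len(x) else 0.0)
    ax.set_xlim((0, lim) if abs_x else (-lim, lim))
    ax.set_ylim(-0.01, max(y_max * 1.3, float(y.max()) * 1.15 + 0.01))
    ax.legend(loc="upper left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
    if coords_path is not None:
        coords.to_csv(coords_path, index=False)
    return fig, coords
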