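"""Pairwise multi-observer agreement for perfusion values.

With N observers every parameter/region cell yields N(N-1)/2 unordered
pairwise comparisons.  Each comparison produces two metrics:

* the intraclass correlation coefficient, two-way absolute-agreement
  single-measure (ICC(A,1)), estimated by REML for the crossed model
  ``value_ip = mu + subject_i + observer_p + eps_ip`` with the two-way
  ANOVA closed form as fallback;
* the mean paired difference scaled to the grand median of that
  parameter at that level (signed percent of median).

Agreement is accepted when ICC >= 0.75 AND |difference| < 20% of the
median (both thresholds configurable).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "AgreementCriteria",
    "ComparisonResult",
    "VALUE_COLUMNS",
    "MEASURES",
    "validate_observer_table",
    "pairwise_comparisons",
    "icc_anova",
    "icc_two_way",
    "icc_pair",
    "grand_median",
    "pairwise_difference",
    "agreement_verdict",
    "quantile_summary",
    "compare_all",
    "summarize_comparisons",
]

#: required columns of an observer-value table
VALUE_COLUMNS = ["observer", "subject", "condition", "parameter", "level",
                 "region_id", "value"]

#: the three analysed perfusion measures as (parameter, condition) keys;
#: MFR is a unitless ratio and carries the pseudo-condition 'ratio'
MEASURES = [("MBF", "rest"), ("MBF", "stress"), ("MFR", "ratio")]

LEVELS = ("global", "territory", "segment")


@dataclass(frozen=True)
class AgreementCriteria:
    """Dual acceptance criterion: ICC >= icc_min and |diff| < diff_max_pct."""

    icc_min: float = 0.75
    diff_max_pct: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.icc_min <= 1.0):
            raise ValueError("icc_min must lie in (0, 1]")
        if self.diff_max_pct <= 0:
            raise ValueError("diff_max_pct must be positive")


@dataclass(frozen=True)
class ComparisonResult:
    """One observer pair at one region for one measure."""

    observer_a: str
    observer_b: str
    parameter: str
    condition: str
    level: str
    region_id: str
    n: int
    icc: float
    mean_diff: float
    pct_of_median: float
    verdict: bool


def validate_observer_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the observer-value table invariants; returns the table."""
    missing = [c for c in VALUE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"observer table lacks columns: {missing}")
    keys = ["observer", "subject", "condition", "parameter", "level", "region_id"]
    if table.duplicated(keys).any():
        raise ValueError("duplicate (observer, subject, condition, parameter, "
                         "region) entries")
    mbf = table.loc[table["parameter"] == "MBF", "value"]
    if (mbf.dropna() < 0).any():
        raise ValueError("MBF values must be nonnegative")
    return table


def pairwise_comparisons(observer_labels) -> list[tuple[str, str]]:
    """All N(N-1)/2 unordered observer pairs in lexicographic order."""
    labels = sorted(set(observer_labels))
    if len(labels) < 2:
        raise ValueError("at least 2 observers are required")
    return list(itertools.combinations(labels, 2))


# ---------------------------------------------------------------------------
# ICC estimation
# ---------------------------------------------------------------------------

def _two_way_sums(y: np.ndarray):
    """Balanced two-way sums of squares (subjects x raters, complete)."""
    n, k = y.shape
    grand = y.mean()
    row = y.mean(axis=1)
    col = y.mean(axis=0)
    ssr = k * np.sum((row - grand) ** 2)
    ssc = n * np.sum((col - grand) ** 2)
    sse = np.sum((y - row[:, None] - col[None, :] + grand) ** 2)
    return ssr, ssc, sse


def icc_anova(y: np.ndarray) -> float:
    """Closed-form two-way absolute-agreement single-measure ICC(A,1).

    ICC = (MSR - MSE) / (MSR + (k-1)MSE + k/n (MSC - MSE)); can be
    negative for discordant data.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    ssr, ssc, sse = _two_way_sums(y)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        warnings.warn("zero total variance; ICC defined as 1", stacklevel=2)
        return 1.0
    return float((msr - mse) / denom)


def _reml_components(y: np.ndarray) -> tuple[float, float, float]:
    """REML variance components (subject, observer, residual).

    For the balanced crossed model the restricted likelihood separates
    over the subject-contrast, observer-contrast and interaction strata
    with variances ls = k*ss + se, lo = n*so + se and se; the criterion

        (n-1) ln ls + SSR/ls + (k-1) ln lo + SSC/lo
        + (n-1)(k-1) ln se + SSE/se

    is minimised under nonnegativity.  In the interior the solution
    coincides with the ANOVA moment estimators.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    ssr, ssc, sse = _two_way_sums(y)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    scale = max(msr, msc, mse, 1e-30)
    floor = 1e-12 * scale

    def nll(p):
        ss, so, se = p
        ls = k * ss + se
        lo = n * so + se
        return ((n - 1) * np.log(ls) + ssr / ls
                + (k - 1) * np.log(lo) + ssc / lo
                + (n - 1) * (k - 1) * np.log(se) + sse / se)

    x0 = np.array([max((msr - mse) / k, floor),
                   max((msc - mse) / n, floor),
                   max(mse, floor)])
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(0.0, None), (0.0, None), (floor, None)],
                   options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500})
    ss, so, se = res.x
    return float(ss), float(so), float(se)


def icc_two_way(y: np.ndarray, method: str = "reml") -> float:
    """ICC(A,1) for an n-subjects x k-raters matrix of paired values.

    ``method='reml'`` (default) estimates variance components by REML
    and returns ss / (ss + so + se); ``'anova'`` uses the mean-squares
    closed form.  Degenerate inputs: zero total variance gives ICC 1
    with a warning; a zero residual stratum falls back to the closed
    form (the two coincide there).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 raters")
    n, k = y.shape
    if n < 3:
        raise ValueError("at least 3 subjects are required")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite (drop missing pairs first)")

    total_ss = np.sum((y - y.mean()) ** 2)
    if total_ss <= 1e-24 * max(1.0, y.mean() ** 2):
        warnings.warn("zero total variance; ICC defined as 1", stacklevel=2)
        return 1.0
    if method == "anova":
        return icc_anova(y)
    if method != "reml":
        raise ValueError(f"unknown ICC method {method!r}")

    _, _, sse = _two_way_sums(y)
    if sse <= 1e-15 * total_ss:  # raters exactly offset/identical
        return icc_anova(y)
    ss, so, se = _reml_components(y)
    return float(ss / (ss + so + se))


def icc_pair(values_a, values_b, method: str = "reml") -> float:
    """ICC(A,1) between two observers' paired per-subject values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value vectors must be 1-D and equal length")
    return icc_two_way(np.column_stack([a, b]), method=method)


# ---------------------------------------------------------------------------
# differences, medians, verdicts
# ---------------------------------------------------------------------------

def grand_median(table: pd.DataFrame, parameter: str, level: str,
                 condition: str | None = None) -> float:
    """Median over ALL pooled values of a parameter at one level.

    Pools across observers, subjects and regions, matching the use of a
    single per-level median as the difference denominator.
    """
    sel = (table["parameter"] == parameter) & (table["level"] == level)
    if condition is not None:
        sel &= table["condition"] == condition
    vals = table.loc[sel, "value"].dropna()
    if vals.empty:
        raise ValueError(
            f"no values for parameter={parameter!r}, level={level!r}, "
            f"condition={condition!r}")
    return float(vals.median())


def pairwise_difference(values_a, values_b, median_ref: float,
                        diff_mode: str = "bias") -> tuple[float, float]:
    """Mean paired difference and its signed percent of the median.

    ``diff_mode='bias'`` (default) is mean(a - b); ``'mad'`` is the mean
    absolute paired difference.
    """
    if median_ref <= 0:
        raise ValueError("median reference must be positive")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if diff_mode == "bias":
        d = float(np.mean(a - b))
    elif diff_mode == "mad":
        d = float(np.mean(np.abs(a - b)))
    else:
        raise ValueError(f"unknown diff_mode {diff_mode!r}")
    return d, 100.0 * d / median_ref


def agreement_verdict(icc: float, pct_of_median: float,
                      criteria: AgreementCriteria = AgreementCriteria()) -> bool:
    """Pass iff ICC >= icc_min AND |pct of median| < diff_max_pct."""
    if not (np.isfinite(icc) and np.isfinite(pct_of_median)):
        raise ValueError("verdict requires finite inputs")
    return bool(icc >= criteria.icc_min
                and abs(pct_of_median) < criteria.diff_max_pct)


def quantile_summary(pct_diffs, q: float = 0.90) -> float:
    """Empirical q-quantile of |percent differences| (linear interpolation)."""
    d = np.abs(np.asarray(pct_diffs, dtype=float))
    if d.size == 0:
        raise ValueError("empty difference list")
    return float(np.quantile(d, q, method="linear"))


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def compare_all(table: pd.DataFrame,
                criteria: AgreementCriteria = AgreementCriteria(),
                diff_mode: str = "bias",
                icc_method: str = "reml") -> pd.DataFrame:
    """Run every pairwise comparison in an observer-value table.

    For each (parameter, condition) measure, level and region, computes
    ICC, mean difference and percent of the level's grand median for all
    observer pairs.  Subjects missing for either observer of a pair are
    dropped listwise for that comparison.
    """
    validate_observer_table(table)
    pairs = pairwise_comparisons(table["observer"].unique())
    rows = []
    for parameter, condition in MEASURES:
        sub = table[(table["parameter"] == parameter)
                    & (table["condition"] == condition)]
        if sub.empty:
            continue
        for level in LEVELS:
            at_level = sub[sub["level"] == level]
            if at_level.empty:
                continue
            med = grand_median(at_level, parameter, level, condition)
            for region_id, grp in at_level.groupby("region_id", sort=True):
                wide = grp.pivot(index="subject", columns="observer",
                                 values="value")
                for oa, ob in pairs:
                    both = wide[[oa, ob]].dropna()
                    n_dropped = len(wide) - len(both)
                    if n_dropped:
                        warnings.warn(
                            f"{n_dropped} subjects dropped listwise for pair "
                            f"({oa}, {ob}) at {parameter}/{condition}/"
                            f"{region_id}", stacklevel=2)
                    a = both[oa].to_numpy()
                    b = both[ob].to_numpy()
                    icc = icc_pair(a, b, method=icc_method)
                    d, pct = pairwise_difference(a, b, med, diff_mode)
                    rows.append({
                        "pair": f"{oa}-{ob}",
                        "observer_a": oa, "observer_b": ob,
                        "parameter": parameter, "condition": condition,
                        "level": level, "region_id": str(region_id),
                        "n": len(both), "icc": icc, "mean_diff": d,
                        "pct_of_median": pct,
                        "verdict": agreement_verdict(icc, pct, criteria),
                    })
    return pd.DataFrame(rows)


def summarize_comparisons(comparisons: pd.DataFrame, table: pd.DataFrame,
                          q: float = 0.90) -> dict:
    """Per-measure, per-level medians, |pct| quantiles and failure counts."""
    out: dict = {"measures": {}, "n_comparisons": int(len(comparisons)),
                 "n_failing": int((~comparisons["verdict"]).sum())}
    for parameter, condition in MEASURES:
        key = f"{condition}_{parameter}" if parameter == "MBF" else parameter
        cmp_sub = comparisons[(comparisons["parameter"] == parameter)
                              & (comparisons["condition"] == condition)]
        if cmp_sub.empty:
            continue
        levels = {}
        for level, grp in cmp_sub.groupby("level"):
            levels[level] = {
                "median": grand_median(table, parameter, level, condition),
                "n_comparisons": int(len(grp)),
                "n_failing": int((~grp["verdict"]).sum()),
                f"q{int(q * 100)}_abs_pct_diff":
                    quantile_summary(grp["pct_of_median"], q),
                "max_abs_pct_diff": float(grp["pct_of_median"].abs().max()),
                "min_icc": float(grp["icc"].min()),
            }
        out["measures"][key] = levels
    return out
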