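"""One-tissue compartment kinetics for dynamic Rb-82 cardiac PET.

The measured myocardial signal is modelled as

    C_PET(t) = (1 - tbv) * Ct(t) + tbv * Ca(t)
    Ct(t)    = K1 * int_0^t Ca(tau) * exp(-k2 * (t - tau)) dtau

where ``Ca`` is the blood-pool (LV cavity) input curve, ``K1`` (mL/min/g)
the uptake rate, ``k2`` (1/min) the washout rate and ``tbv`` the
blood-volume/spillover fraction.  ``K1`` maps to myocardial blood flow
through the flow-dependent extraction fraction

    K1 = MBF * (1 - a * exp(-b / MBF))

with the Rb-82 constants ``a = 0.77`` and ``b = 0.63`` mL/min/g.

Time is handled internally in minutes (MBF and K1 are per-minute
quantities); frame schedules are specified in seconds and converted on
construction.  The blood-pool curve is treated as piecewise linear
through the frame mid-times, which makes the convolution above exact
per linear segment -- no generic quadrature is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "ExtractionParams",
    "KineticFit",
    "FitOptions",
    "default_schedule",
    "tissue_response",
    "tissue_concentration",
    "model_pet_signal",
    "fit_1tcm",
    "mbf_to_k1",
    "k1_to_mbf",
    "extraction_fraction",
    "compute_mfr",
]

BLOOD_POOL_REGION = "LV_cavity"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic-scan frame timing, stored in seconds.

    Frames must be non-overlapping with strictly increasing start times;
    gaps are allowed.
    """

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame starts and durations must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[1:] < (start[:-1] + dur[:-1]) - 1e-9):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start_s.size)

    @property
    def start_min(self) -> np.ndarray:
        return self.frame_start_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.frame_duration_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times in minutes (start + duration / 2)."""
        return (self.frame_start_s + self.frame_duration_s / 2.0) / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return (self.frame_start_s + self.frame_duration_s) / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.frame_duration_s))


def default_schedule() -> FrameSchedule:
    """The acquisition schedule: 12 x 8 s, 5 x 12 s, 30 s, 60 s, 2 x 120 s.

    21 frames covering 486 s (8.1 min) from injection.
    """
    durations = np.concatenate(
        [np.full(12, 8.0), np.full(5, 12.0), [30.0, 60.0], np.full(2, 120.0)]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/mL) for one region."""

    schedule: FrameSchedule
    activity: np.ndarray
    region_id: str = ""
    is_blood_pool: bool = False

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"expected {self.schedule.n_frames} activity values, got {act.shape}"
            )
        if not np.all(np.isfinite(act)):
            raise ValueError("activity values must be finite")

    def interp_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear representation: (0, 0) then (mid-time, value).

        Beyond the last mid-time the curve is held constant.
        """
        t = np.concatenate([[0.0], self.schedule.mid_min])
        c = np.concatenate([[0.0], self.activity])
        return t, c


@dataclass(frozen=True)
class ExtractionParams:
    """Flow-dependent extraction constants for Rb-82: E(m) = 1 - a*exp(-b/m)."""

    a: float = 0.77
    b: float = 0.63

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ValueError("extraction parameter a must lie in (0, 1)")
        if self.b <= 0:
            raise ValueError("extraction parameter b must be positive")


@dataclass(frozen=True)
class KineticFit:
    """Fitted one-tissue-compartment parameters for one TAC."""

    K1: float
    k2: float
    tbv: float
    mbf: float
    wrss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be nonnegative")
        if not (0.0 <= self.tbv < 1.0):
            raise ValueError("blood-volume fraction must lie in [0, 1)")


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings for :func:`fit_1tcm`.

    Bounds and the two deterministic start points give reproducible fits;
    ``weights_mode`` is 'duration' (w_i = frame duration, the conventional
    dynamic-PET weighting) or 'uniform'.
    """

    weights_mode: str = "duration"
    x0: tuple[float, float, float] = (0.5, 0.1, 0.3)
    x0_restart: tuple[float, float, float] = (1.5, 0.3, 0.5)
    bounds_lo: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bounds_hi: tuple[float, float, float] = (5.0, 5.0, 0.95)

    def weights(self, schedule: FrameSchedule) -> np.ndarray:
        if self.weights_mode == "duration":
            return schedule.duration_min.copy()
        if self.weights_mode == "uniform":
            return np.ones(schedule.n_frames)
        raise ValueError(f"unknown weights_mode {self.weights_mode!r}")


# ---------------------------------------------------------------------------
# extraction fraction / MBF conversion
# ---------------------------------------------------------------------------

def extraction_fraction(mbf, params: ExtractionParams = ExtractionParams()):
    """E(m) = 1 - a*exp(-b/m); decreasing in m, range (1-a, 1)."""
    m = np.asarray(mbf, dtype=float)
    if np.any(m < 0):
        raise ValueError("MBF must be nonnegative")
    with np.errstate(divide="ignore"):
        e = 1.0 - params.a * np.exp(-np.divide(params.b, m, where=m > 0,
                                               out=np.full_like(m, np.inf)))
    e = np.where(m == 0, 1.0, e)
    return e if e.ndim else float(e)


def mbf_to_k1(mbf, params: ExtractionParams = ExtractionParams()):
    """K1 = MBF * E(MBF), continuously extended to K1(0) = 0."""
    m = np.asarray(mbf, dtype=float)
    if np.any(m < 0):
        raise ValueError("MBF must be nonnegative")
    k1 = m * np.asarray(extraction_fraction(m, params))
    return k1 if k1.ndim else float(k1)


def k1_to_mbf(k1, params: ExtractionParams = ExtractionParams()):
    """Invert the extraction relation by bracketed root finding.

    K1 = m*(1 - a*exp(-b/m)) is strictly increasing in m, so the root is
    unique; solved to |dm| < 1e-12 absolute / 1e-12 relative.
    """
    k1_arr = np.asarray(k1, dtype=float)
    if np.any(k1_arr < 0):
        raise ValueError("K1 must be nonnegative")

    def _solve(v: float) -> float:
        if v == 0.0:
            return 0.0
        # K1 >= (1-a)*m gives the upper bracket
        hi = v / (1.0 - params.a) + 1.0
        return brentq(lambda m: mbf_to_k1(m, params) - v, 1e-15, hi,
                      xtol=1e-12)

    out = np.vectorize(_solve, otypes=[float])(k1_arr)
    return out if out.ndim else float(out)


def compute_mfr(stress_mbf, rest_mbf):
    """Myocardial flow reserve: stress MBF / rest MBF, elementwise.

    Entries with nonpositive rest flow are flagged missing (NaN) rather
    than propagated as infinities.
    """
    s = np.asarray(stress_mbf, dtype=float)
    r = np.asarray(rest_mbf, dtype=float)
    bad = ~(r > 0)
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} entries with nonpositive rest MBF "
                      "set to missing in MFR", stacklevel=2)
    mfr = np.divide(s, r, where=~bad, out=np.full(np.broadcast(s, r).shape, np.nan))
    return mfr if mfr.ndim else float(mfr)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _phi(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi1 = (1-e^-x)/x and phi2 = (1-(1+x)e^-x)/x^2, series-safe near 0."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-4
    xs = np.where(small, 1.0, x)  # avoid 0/0; overwritten below
    ex = np.exp(-xs)
    p1 = (1.0 - ex) / xs
    p2 = (1.0 - (1.0 + xs) * ex) / xs**2
    p1 = np.where(small, 1.0 - x / 2.0 + x**2 / 6.0, p1)
    p2 = np.where(small, 0.5 - x / 3.0 + x**2 / 8.0, p2)
    return p1, p2


def _ct_on_grid(K1: float, k2: float, tk: np.ndarray, ck: np.ndarray,
                t: np.ndarray) -> np.ndarray:
    """Exact 1TCM tissue curve at sorted times ``t``.

    The input is piecewise linear through knots (tk, ck) and constant
    after the last knot.  Per linear segment [t0, t1] with
    Ca(tau) = a + b*(tau - t0):

        Ct(t1) = Ct(t0)*e^(-k2*dt) + K1*dt*((a + b*dt)*phi1 - b*dt*phi2)

    with phi1/phi2 evaluated at k2*dt, which is the analytic convolution
    integral -- exact for any k2 including 0.
    """
    grid = np.union1d(tk, t)
    grid = grid[grid >= tk[0]]
    ca = np.interp(grid, tk, ck)
    dt = np.diff(grid)
    a = ca[:-1]
    b = np.where(dt > 0, np.diff(ca) / np.where(dt > 0, dt, 1.0), 0.0)
    x = k2 * dt
    p1, p2 = _phi(x)
    seg = K1 * dt * ((a + b * dt) * p1 - b * dt * p2)
    decay = np.exp(-x)
    ct_grid = np.empty(grid.size)
    ct_grid[0] = 0.0
    for i in range(dt.size):
        ct_grid[i + 1] = ct_grid[i] * decay[i] + seg[i]
    out = np.interp(t, grid, ct_grid)  # exact: every t is a grid point
    return np.where(t < tk[0], 0.0, out)


def tissue_concentration(K1: float, k2: float, input_tac: TimeActivityCurve,
                         t) -> np.ndarray:
    """Evaluate Ct(t) = K1 * (Ca * exp(-k2 .)) (t) at arbitrary times (min)."""
    if K1 < 0 or k2 < 0:
        raise ValueError("rate constants must be nonnegative")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tk, ck = input_tac.interp_knots()
    return _ct_on_grid(K1, k2, tk, ck, t)


def tissue_response(K1: float, k2: float, input_tac: TimeActivityCurve,
                    dt_min: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Tissue concentration on a fine uniform grid over the scan window.

    Returns (times_min, Ct).  The grid step defaults to 0.01 min; the
    values themselves are exact regardless of the step.
    """
    t_end = float(input_tac.schedule.end_min[-1])
    t = np.arange(0.0, t_end + dt_min / 2.0, dt_min)
    return t, tissue_concentration(K1, k2, input_tac, t)


def _frame_average_ct(K1: float, k2: float, input_tac: TimeActivityCurve,
                      schedule: FrameSchedule) -> np.ndarray:
    """Exact frame averages of Ct over each [start, start+duration].

    For k2 > 0 uses the ODE identity  int Ct = (K1 * int Ca - dCt) / k2
    (both terms exact).  For k2 ~ 0 the tissue curve is piecewise
    quadratic, integrated exactly by Simpson on each linear-input segment.
    """
    tk, ck = input_tac.interp_knots()
    t0 = schedule.start_min
    t1 = schedule.end_min
    dur = schedule.duration_min

    # exact integral of the piecewise-linear input over each frame
    def ca_frame_integral() -> np.ndarray:
        out = np.empty(t0.size)
        for i, (lo, hi) in enumerate(zip(t0, t1)):
            pts = np.union1d([lo, hi], tk[(tk > lo) & (tk < hi)])
            out[i] = np.trapezoid(np.interp(pts, tk, ck), pts)
        return out

    if k2 * (t1[-1] - t0[0]) > 1e-6:
        ct_lo = tissue_concentration(K1, k2, input_tac, t0)
        ct_hi = tissue_concentration(K1, k2, input_tac, t1)
        int_ca = ca_frame_integral()
        return (K1 * int_ca - (ct_hi - ct_lo)) / (k2 * dur)

    out = np.empty(t0.size)
    for i, (lo, hi) in enumerate(zip(t0, t1)):
        pts = np.union1d([lo, hi], tk[(tk > lo) & (tk < hi)])
        mids = (pts[:-1] + pts[1:]) / 2.0
        ct_p = tissue_concentration(K1, k2, input_tac, pts)
        ct_m = tissue_concentration(K1, k2, input_tac, mids)
        h = np.diff(pts)
        out[i] = np.sum(h / 6.0 * (ct_p[:-1] + 4.0 * ct_m + ct_p[1:]))
    return out / dur


def model_pet_signal(K1: float, k2: float, tbv: float,
                     input_tac: TimeActivityCurve,
                     schedule: FrameSchedule | None = None,
                     region_id: str = "model") -> TimeActivityCurve:
    """Frame-averaged model signal (1-tbv)*Ct + tbv*Ca on a schedule."""
    if K1 < 0 or k2 < 0:
        raise ValueError("rate constants must be nonnegative")
    if not (0.0 <= tbv <= 1.0):
        raise ValueError("tbv must lie in [0, 1]")
    if schedule is None:
        schedule = input_tac.schedule
    if schedule.n_frames != input_tac.schedule.n_frames or not np.allclose(
            schedule.frame_start_s, input_tac.schedule.frame_start_s):
        raise ValueError("model schedule must match the input-curve schedule")

    # measured blood values are already frame averages of Ca; use them
    # directly for the spillover term (the piecewise-linear interpolant
    # is only needed inside the convolution)
    ca_avg = input_tac.activity

    if tbv == 1.0:
        return TimeActivityCurve(schedule, ca_avg, region_id=region_id)
    if K1 == 0.0:
        return TimeActivityCurve(schedule, tbv * ca_avg, region_id=region_id)

    ct_avg = _frame_average_ct(K1, k2, input_tac, schedule)
    sig = (1.0 - tbv) * ct_avg + tbv * ca_avg
    return TimeActivityCurve(schedule, sig, region_id=region_id)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_1tcm(measured: TimeActivityCurve, input_tac: TimeActivityCurve,
             options: FitOptions = FitOptions(),
             extraction: ExtractionParams = ExtractionParams()) -> KineticFit:
    """Weighted nonlinear least-squares fit of (K1, k2, tbv) to one TAC.

    Minimises sum_i w_i (y_i - yhat_i)^2 with bounded trust-region least
    squares from a fixed start, retrying once from a second deterministic
    start if the first attempt does not converge.  MBF is derived from K1
    through the extraction relation.  An all-zero TAC short-circuits to a
    zero fit with a warning; the converged flag reports optimiser success
    honestly.
    """
    if measured.schedule.n_frames != input_tac.schedule.n_frames or not np.allclose(
            measured.schedule.frame_start_s, input_tac.schedule.frame_start_s):
        raise ValueError("measured and input TACs must share one schedule")
    if measured.schedule.n_frames < 6:
        raise ValueError("at least 6 frames are required for a 3-parameter fit")
    y = measured.activity
    if not np.all(np.isfinite(y)):
        raise ValueError("measured activities must be finite")
    if np.all(y == 0):
        warnings.warn("all-zero measured TAC; returning zero-uptake fit",
                      stacklevel=2)
        return KineticFit(K1=0.0, k2=0.0, tbv=0.0, mbf=0.0, wrss=0.0,
                          converged=True)

    w = options.weights(measured.schedule)
    sw = np.sqrt(w)
    schedule = measured.schedule

    def residuals(p):
        model = model_pet_signal(p[0], p[1], p[2], input_tac, schedule)
        return sw * (model.activity - y)

    bounds = (np.array(options.bounds_lo), np.array(options.bounds_hi))
    res = least_squares(residuals, np.array(options.x0), bounds=bounds,
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not res.success:
        res2 = least_squares(residuals, np.array(options.x0_restart),
                             bounds=bounds, method="trf",
                             xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if res2.success or res2.cost < res.cost:
            res = res2

    K1, k2, tbv = (float(v) for v in res.x)
    mbf = k1_to_mbf(K1, extraction) if K1 > 0 else 0.0
    return KineticFit(K1=K1, k2=k2, tbv=tbv, mbf=float(mbf),
                      wrss=float(2.0 * res.cost), converged=bool(res.success))
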