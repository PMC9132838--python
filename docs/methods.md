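# Methods

## Kinetic model

Rb-82 exchange between arterial blood and myocardium is described by a
one-tissue compartment model. With `Ca(t)` the blood-pool (LV cavity)
concentration and `Ct(t)` the tissue concentration,

    dCt/dt = K1·Ca(t) − k2·Ct(t),      Ct(0) = 0,

and the measured PET signal of a myocardial region mixes tissue and blood:

    C_PET(t) = (1 − V_b)·Ct(t) + V_b·Ca(t),

where `V_b` (`tbv` in the code) is the blood-volume/spillover fraction.
Because Rb-82 extraction falls with flow, K1 underestimates flow at high
flow; the flow-dependent extraction model

    K1 = MBF·E(MBF),   E(m) = 1 − a·e^(−b/m),   a = 0.77, b = 0.63 mL/min/g

converts between the two. `E` is strictly decreasing with range
(1 − a, 1) and `m·E(m)` strictly increasing, so the inverse used by
`k1_to_mbf` exists and is found by bracketed root-finding (Brent,
`xtol = 1e-12`; round trip verified to 1e-8 over MBF ∈ [0.01, 10]).
MFR is computed per subject and region as stress MBF / rest MBF, never
as a ratio of cohort means; nonpositive rest flow flags the entry
missing rather than dividing.

Time is handled internally in minutes, because K1, k2 and MBF are
per-minute quantities; frame schedules are specified in seconds and
converted on construction. The default dynamic schedule is 21 frames —
12 × 8 s, 5 × 12 s, 1 × 30 s, 1 × 60 s, 2 × 120 s — totalling 486 s.

### Numerical scheme

The blood TAC is interpreted as piecewise linear through the frame
mid-times (start + duration/2), starting from (0, 0) and held constant
after the last mid-time. Over each linear input segment the convolution
integral has a closed form, so `Ct` is evaluated exactly by a one-pass
recursion (series expansions guard `k2·Δt < 1e-4` against cancellation).
Frame averages of `Ct` use the ODE identity
`∫Ct = (K1·∫Ca − ΔCt)/k2` — again exact — with an exact Simpson rule on
the piecewise-quadratic limit when `k2 ≈ 0`. The spillover term uses the
measured blood frame values directly, since those already are frame
averages of `Ca`. No generic quadrature appears anywhere in the model,
so a noise-free forward-simulate/refit loop closes to machine precision.

### Fitting

`fit_1tcm` minimises `Σ wᵢ(yᵢ − ŷᵢ)²` over (K1, k2, V_b) with bounded
trust-region least squares (`scipy.optimize.least_squares`, bounds
K1 ∈ [0, 5] mL/min/g, k2 ∈ [0, 5] /min, V_b ∈ [0, 0.95]), from the fixed
start (0.5, 0.1, 0.3) with one deterministic restart from (1.5, 0.3, 0.5)
if the first attempt fails — fits are fully reproducible. Default
weights are the frame durations (`wᵢ = Δtᵢ` in minutes), the
conventional dynamic-PET choice that downweights the short early frames'
noisier averages; uniform weighting is selectable. An all-zero TAC
returns a zero-uptake fit with a warning instead of raising, and the
`converged` flag reports optimiser success honestly. No delay or
dispersion correction is applied to the input function.

## Heart model

Segments 1–17 follow the AHA convention; territories are
LAD {1, 2, 7, 8, 13, 14, 17}, RCA {3, 4, 9, 10, 15},
LCx {5, 6, 11, 12, 16}. The apical segment 17 is assigned to LAD, which
is configurable because conventions differ. Aggregation to territory and
global curves is a weight-normalised framewise mean with equal weights
by default (relative myocardial volumes can be supplied) and happens
before fitting: global MBF is the fit of the global TAC. For spatially
homogeneous flow the fitted MBF is identical at all three levels; more
generally, segments sharing k2 and V_b make the aggregate signal linear
in K1, so the aggregate fit returns the weighted-mean K1.

## Agreement statistics

With N observers there are N(N−1)/2 unordered pairs (6 for four
observers), giving per parameter 6 global, 18 territory and 102
segmental comparison cells. For each cell:

* **ICC** — two-way absolute-agreement single-measure ICC(A,1) for the
  crossed model `value_ip = μ + subject_i + observer_p + ε_ip`. The
  estimator is REML: for balanced complete data the restricted
  likelihood separates over the subject-contrast, observer-contrast and
  interaction strata, and the criterion is minimised directly over the
  three variance components under nonnegativity (L-BFGS-B from the
  moment estimates). In the interior this coincides with the two-way
  ANOVA closed form (asserted to 1e-6 in tests, and cross-checked
  against an independent implementation); when a moment estimate is
  negative, REML clamps the component at zero, keeping ICC in [0, 1].
  Absolute agreement (including the observer variance in the
  denominator) is the variant consistent with pairing the ICC with
  absolute differences. Zero total variance is reported as ICC = 1 with
  a warning; subjects missing for either observer of a pair are dropped
  listwise for that comparison with a logged count.
* **Difference** — the signed mean paired difference, expressed as
  percent of the grand median of that parameter at that level (pooled
  over observers, subjects and regions). The signed bias is the default
  (`diff_mode="bias"`) because the biplot's symmetric ±20 % axis implies
  a signed quantity; the mean absolute difference is available as
  `diff_mode="mad"`.
* **Verdict** — pass iff ICC ≥ 0.75 and |difference| < 20 % of the
  median. The ICC threshold is inclusive and the difference threshold
  strict; both are configurable. Raising ICC or shrinking |difference|
  can never flip a pass into a fail.

Quantile summaries report the empirical q-quantile (linear-interpolation
convention) of the absolute percent differences per measure and level.
Bland–Altman limits of agreement are deliberately out of scope: with
more than two raters the pairwise ICC + scaled-difference criterion is
the applicable tool.

## Biplot

Each comparison is a point at (percent-of-median difference, 1 − ICC);
the origin is the identity point. The rectangle spans ±`diff_max_pct` in
x and [0, 1 − `icc_min`] in y (±20 % × 0.25 by default) and rescales
with the criteria; point-in-rectangle classification (x strict, y
inclusive) equals the verdict for every point. Labels combine the
region code with the pair's ordinal in lexicographic order (`s14-3`).
Marker styling is not meant to replicate any particular figure.

## Synthetic cohort

The generator emulates the statistical structure of a 48-subject,
4-observer rest/stress study; every generator is a pure function of
(spec, seed).

* **Subjects** — global rest MBF ~ N(1.11, 0.36²) mL/min/g and
  MFR ~ N(2.18, 0.82²), truncated at zero (the truncation point is ≈3 SD
  below the mean, so the moment distortion is negligible); stress =
  rest × MFR. Truncated normals rather than lognormals match a
  mean ± SD calibration directly.
* **Segments** — segment value = global × (1 + δ), δ ~ N(0, 0.10²) drawn
  independently per condition. The 10 % heterogeneity default mirrors
  the observed spread of segmental means around the global mean.
* **Input function** — a 30-s constant-activity square-wave infusion
  convolved with the bi-exponential impulse response
  `A1·e^(−λ1 t) + A2·e^(−λ2 t)` (defaults A1 = 1, λ1 = 0.5/min, A2 = 0.2,
  λ2 = 0.05/min, peak scale 50 kBq/mL), chosen to give a realistic
  peaked-then-plateau Rb-82 blood curve; frame averages are closed-form.
* **Dynamic TACs** — per segment K1 derives from true MBF via the
  extraction relation with fixed k2 = 0.15/min and V_b = 0.35; frame
  noise is Gaussian with SD = `noise_cv`·value/√(duration in seconds),
  the 1/√counts scaling of frame statistics.
* **Observers** — measured value = truth + bias_p + ε, with
  bias_p ~ N(0, σ_obs²) per observer and ε ~ N(0, σ_res²) per
  measurement; negatives clip at zero with a recorded count, and each
  observer's territory/global values and MFR are recomputed from its own
  segment values. The implied true ICC
  σ²_subject/(σ²_subject + σ²_obs + σ²_res) is exposed on the spec and
  verified against the estimator in simulation. Defaults
  σ_obs = 0.02, σ_res = 0.05 mL/min/g encode the intended
  high-reproducibility regime (implied global rest-MBF ICC ≈ 0.98,
  pairwise biases of a few percent of the median), i.e. an
  excellent-agreement scenario; they were set from the target moments,
  not fitted to any outcome.

What the generator does **not** emulate: observer effects act additively
on values, not on segmentations in image space, so it cannot produce the
spatially structured, flow-dependent disagreements a misplaced axis
causes (e.g. a basal-septal membranous segment); there is no attenuation,
scatter, motion or reconstruction artefact, no arterial delay/dispersion,
and subject flows are independent across subjects. Passing tests
therefore validate the estimation and decision machinery under the
assumed variance structure — not the clinical reproducibility of any
particular software on real scans.

## Problem sizes and runtime choices

The default pipeline analyses all 48 subjects' observer tables but
forward-simulates and refits dynamic studies for 4 subjects
(`n_dynamic_subjects`, 168 fits) as a kinetics quality check; the
acceptance script additionally runs the noisy circle test over all
48 subjects' rest segment fields (816 fits) and a 500-replicate ICC
calibration. Unit tests use smaller cohorts (3–12 subjects, 60–300
replicates) chosen to keep the whole suite around a minute while leaving
the Monte-Carlo assertions' sampling error well inside their tolerances.

## Known limitations

* The ICC is computed per pair (k = 2) rather than from one joint
  four-observer model, matching the pairwise design; the two differ when
  observer variances are heterogeneous.
* REML here assumes balanced complete data after listwise dropping;
  heavily unbalanced designs would need the general mixed-model path.
* The extraction constants (a, b) are treated as exact; their
  uncertainty propagates directly into MBF and is not modelled.
* `k2` and `V_b` are fitted freely; on very noisy curves they correlate
  with K1 and can hit bounds, which the `converged` flag and `wrss`
  expose but the pipeline does not automatically reject.
* MFR is a ratio, so it is unstable wherever rest flow approaches zero:
  the zero-truncated cohort occasionally produces a subject whose rest
  segment value is far below the physiologic range, and a single such
  subject can collapse a segmental MFR ICC for some seeds. Global and
  territory levels average this away; the instability is a property of
  the ratio, not of the estimator, and is left visible rather than
  clipped.
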