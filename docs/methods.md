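# Methods

## Model

A cell confined to a ring-shaped micro-lane is described by its unwrapped
angular position φ(t), sampled uniformly (default Δt = 10 min, a typical
live-cell imaging cadence that resolves multi-hour dwell times). Motion is
modeled as a two-state alternating renewal process:

* **RUN** — ballistic motion along the lane at a per-cell speed v, in a
  direction that may reverse between runs;
* **REST** — no net motion; position fluctuates randomly.

Dwell times in each state are assumed exponential (memoryless), T_run ~
Exp(τ_run), T_rest ~ Exp(τ_rest); the survival function of either state is
then log-linear, log S(t) = −t/τ + c, which is what the estimation stage
fits. Under stationarity the long-run fraction of time in the run state is
P_run = τ_run/(τ_run + τ_rest), which serves as an internal consistency
check between two independently estimated quantities.

All angles are radians, positive counter-clockwise (atan2 convention);
arc positions and velocities use the ring radius (default 75 µm, i.e. a
150 µm ring). Time is hours throughout. Only magnitudes matter downstream,
so the sign convention is free.

## Trajectory handling

Cartesian tracking coordinates are projected to angles via atan2 about the
ring center; the radial residual |r − R| is kept per point for quality
control, and cells whose mean radial deviation exceeds 20% of the radius
are flagged (not dropped) as possibly off-lane. Raw angles are unwrapped by
shifting each step into (−π, π); a step of magnitude exactly π is reported
as an error rather than resolved arbitrarily. Tracks need at least two
points; sampling must be uniform to 10⁻⁶ relative tolerance.

## Run/rest segmentation

The segmenter is a deterministic threshold scheme on the tangential
velocity, with every knob exposed (`SegmentationParams`) and the segmenter
itself pluggable (any callable `(VelocitySeries, SegmentationParams) ->
[StateSegment]`), so a probabilistic two-state classifier can be swapped in
without touching downstream estimators.

1. φ is smoothed with a centered moving average of length `smooth_window`
   (window shrinks symmetrically at track edges) and differentiated with a
   central 3-point stencil (one-sided at the ends); v_tang = R·dφ/dt.
2. A frame is RUN iff |v_tang| ≥ `v_threshold` (default 6 µm/h). A sign
   change of v_tang inside a run splits it (`reversal_breaks_run`), so a
   direct reversal does not average into a spurious rest.
3. Each RUN/REST boundary is re-placed at the frame where |v_tang| crosses
   half the adjacent run's own mean speed (`refine_boundaries`, default
   on). Rationale: with a fixed low threshold, the velocity ramp produced
   by smoothing/differencing crosses the threshold well inside the rest for
   any cell faster than ~2× threshold, so runs are systematically widened
   and rests narrowed; the half-speed point is the midpoint of the ramp and
   is unbiased independent of the cell's speed.
4. Segments shorter than `min_state_duration` are absorbed into a
   neighbor, shortest first (earliest on ties), each into its longer
   neighbor (preceding one on ties), until all segments meet the minimum
   or one remains. Segment boundaries sit midway between adjacent frames,
   so the segments of a cell tile [t_first, t_last] exactly.

Adjacent segments never share both label and direction; strict RUN/REST
alternation holds except where a reversal split two runs of opposite
direction.

**Resolution–noise trade-off.** `smooth_window` and `min_state_duration`
jointly set the shortest detectable state. Any state shorter than the
effective blur is invisible, and an absorbed or missed state *merges its
two neighbors*; because a geometric sum of exponentials is again
exponential with mean τ/(1−p), this inflates the fitted lifetime of the
neighboring state multiplicatively by the miss probability p — a slope
effect the fit cannot remove. Short-time distortions of the opposite kind
(boundary jitter, spurious brief states) only shift or rescale the
survival curve and are absorbed by the fit intercept, which is exactly why
the fit range excludes t < 2 h. Defaults are therefore chosen as small as
the noise floor allows: 0.2 h for both (≈ one frame at 10-min cadence,
i.e. a plain central difference and an absorber that only removes
single-frame flicker). With micrometers-scale tracking noise, raise both
to ~0.5 h and expect a few-percent upward bias on the τ's via the
mechanism above.

## Dwell-time statistics

* **Censor-horizon rule.** A state enters the dwell sample iff it starts
  at least 16 h (`censor_horizon`) before the end of its track. States
  still ongoing at track end are kept with their observed duration and a
  censoring flag — their observed duration is then ≥ 16 h, so S(t) on the
  fit range is unaffected. States touching the track start are kept (the
  rule conditions only on distance to track end).
* **Survival function.** S(t) = #(T > t)/n on the grid t = 0, Δt, …, 16 h.
* **Fit.** log S(t) is fitted with f(t) = −t/τ + c on t ∈ [2, 16] h by
  weighted least squares; grid points with S = 0 are dropped (log
  undefined) and the rest are weighted by the inverse delta-method
  binomial variance of log S, w ∝ S/(1−S). Equal weighting would let the
  deep tail — where log S rests on a handful of surviving states and
  fluctuates by O(1) — dominate; at the calibration scenario below it
  roughly doubles the estimator's spread. On exact log-linear input the
  fit is exact regardless of weights. A non-negative slope raises a
  degenerate-fit error; fewer than 3 usable points raises a fit error. In
  the population pipeline a failed τ fit becomes a missing value with a
  diagnostic, and the remaining parameters are still reported.
* **99% CI.** τ = −1/slope is monotone in the slope, so the slope's 99%
  interval propagates directly. When the dwell sample is available
  (`fit_tau_from_sample`, used by the pipeline), the slope interval is the
  0.5–99.5 percentile range over 200 bootstrap resamples of the dwell
  sample (fixed internal resampling seed, so outputs stay deterministic).
  The residual-based t interval (kept in the curve-level `fit_tau`)
  treats the correlated grid points of one empirical survival curve as
  independent observations and measures at far below nominal coverage; the
  bootstrap interval reflects the estimator's true replicate spread. If an
  upper slope bound reaches 0 the upper τ bound is infinite.

## The five estimators

* **v_run**: per cell, mean |v_tang| over RUN frames; population value is
  the unweighted mean over cells with its standard error (each cell counts
  equally — matching per-cell presentations of such data; pooling all run
  frames instead is available via `pool_frames`). Cells with no run frames
  have undefined v_run, are excluded from the mean, and count toward the
  immobile fraction.
* **P_run**: per cell, run time / track duration (complement of rest
  fraction by construction); population mean ± SE over cells.
* **q**: per cell, (max φ − min φ)/Σ|Δφ|; bounded in [0, 1] on a 1D
  coordinate. Zero-path cells are undefined and excluded (with a logged
  count) but still counted in P_run and the immobile fraction.
* **τ_run, τ_rest**: population-level fits as above.
* **immobile fraction**: share of cells whose whole track is one REST
  segment.

All estimators are invariant under φ → −φ. Conditions are compared with
two-sided Welch t-tests on per-cell values (pooled-variance optional);
Welch is the safer default under unequal spread. The τ's, being single
population-level fits, are compared by 99%-CI non-overlap instead.

## Simulator

`simulate_population` draws, per cell: a lognormal speed (median 30 µm/h,
log-sd 0.3 — a broad, strictly positive spread as seen across real
populations); an immobile flag (i.i.d. Bernoulli, so per-cell statistics of
independent populations are exchangeable and between-condition tests stay
calibrated); and an alternating dwell sequence started in RUN with
probability τ_run/(τ_run+τ_rest). Because exponential residual lifetimes
are again exponential, fresh draws with that initial-state probability give
an exactly stationary process and unbiased P_run from t = 0. Within runs
the per-frame step is dir·(v + jitter)·Δt/R (jitter sd 3 µm/h); each new
run reverses direction with probability 0.5; rests add Gaussian positional
noise of sd 0.3 µm per frame (apparent rest speeds ≲ 2 µm/h, well under
the 6 µm/h threshold — a high-SNR but not noise-free regime). All
randomness flows from one seed through per-cell `SeedSequence` substreams:
bitwise reproducible, and each cell independent of population size.

Two preset scenarios are shipped for directional testing: "ctrl-like"
(v 30 µm/h, τ_run 4 h, τ_rest 2 h, 10% immobile) and "induced-like"
(v 20 µm/h, τ_run 2 h, τ_rest 6 h, 30% immobile). They are plausible
motile/low-motility pairs for exercising the comparison machinery, not
measurements.

**What the simulator does not emulate:** tracking noise beyond small
Gaussian wiggle (no outliers, no identity switches, no missed frames),
non-exponential (e.g. refractory) dwell behavior, speed drift within a
cell, interactions between rings, or image-level artifacts. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under the stated model, not robustness to every failure mode of real
tracking data.

## Validation scenarios and problem sizes

Recovery and calibration use 300 cells × 48 h at Δt = 10 min with
τ_run = 2 h, τ_rest = 4 h and no immobile cells: the τ's and
P_run = 1/3 are then exact ground truths of the mobile dynamics. Immobile
cells are deliberately excluded from this scenario because their
never-ending rests add a constant to the rest survival tail — a genuine
data feature (it visibly raises τ_rest in the README example) but one that
makes "true τ_rest" ill-defined; immobile-fraction recovery is validated
separately. CI calibration uses 200 replicates of this scenario;
between-condition type-I error uses 200 pairs of independent 100-cell
populations; condition discrimination uses the preset scenario pair at 100
cells each. At these sizes the observed behavior is: both τ's recovered
within a few percent (replicate sd ≈ 5%), P_run within 0.02 of 1/3,
frame-label accuracy ≈ 97%, 99%-CI coverage for τ_run ≈ 95%, and
per-parameter type-I rates consistent with 5%.

## Numerical choices and degenerate inputs

* Smoothing windows are converted to an odd frame count (rounded), so the
  moving average is always centered.
* Segment boundaries at frame midpoints; absorption tie-breaks as above —
  all deterministic.
* Empty masks, multi-component masks, center-coincident points, non-uniform
  sampling, single-point cells, empty dwell samples and degenerate
  variances raise typed errors (`InputError`/`ConfigurationError`/
  `EstimationError` hierarchies); the CLI maps these to exit codes 2/3/4.
* Feret diameters use convex-hull vertices of pixel centers; the minimum
  Feret scans orientations on a 1° grid (≤ ~0.5% error for smooth convex
  shapes, balancing cost). A 1-pixel-wide line gets min spread 1 px (the
  pixel footprint) to keep the shape factor in (0, 1].
* JSON outputs round floats to 9 significant digits for byte-stable
  re-runs.

## Known limitations

* The threshold segmenter assumes run speeds well above `v_threshold`;
  cells with speeds near the threshold are partly classified as resting
  (visible as a slight low bias of population v_run for broad speed
  distributions).
* τ estimates carry a small positive bias (~3–5% at the calibration
  scenario) from states shorter than one frame, which no classifier at
  this sampling rate can resolve.
* Censoring is handled only through the 16-h horizon rule; there is no
  Kaplan–Meier machinery, and no parametric dwell families other than the
  exponential.
* The morphology module consumes masks; segmentation of fluorescence
  images into masks is upstream and out of scope.
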