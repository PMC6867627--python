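"""Five-parameter motility fingerprint of a cell population.

From segmented trajectories this module estimates, per cell and per
population:

* ``v_run``   — run velocity, the mean absolute tangential velocity over
  RUN-state frames, v_run = <|v_tang|> (um/h);
* ``tau_run``, ``tau_rest`` — characteristic state lifetimes, from a
  log-linear fit of the dwell-time survival function S(t) = P(T > t):
  log S(t) is fitted by f(t) = -(1/tau) t + c on t in [2, 16] h (very small
  times deviate from exponential behavior and are absorbed by the intercept);
* ``P_run``   — fraction of observation time spent in the run state;
* ``q``       — persistence, (max phi - min phi) / total path length.

To limit censoring bias from the finite observation window, only states that
start at least ``censor_horizon`` (16 h) before the end of their cell track
enter the dwell-time sample; the fit range for S(t) ends at the same horizon,
so a state still ongoing at track end (right-censored) has an observed
duration >= the horizon and cannot distort S(t) inside the fit range.

Uncertainties follow the population-level convention of the assay: standard
errors over cells for v_run, P_run and q; a 99% confidence interval of the
log-survival fit for the taus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, EstimationError, FitError
from .io import Trajectory, TrajectoryCollection
from .segmentation import (
    REST,
    RUN,
    SegmentationParams,
    Segmenter,
    StateSegment,
    VelocitySeries,
    frame_labels,
    segment_states,
    tangential_velocity,
)

logger = logging.getLogger(__name__)

DEFAULT_CENSOR_HORIZON = 16.0
DEFAULT_FIT_RANGE = (2.0, 16.0)


# ---------------------------------------------------------------------------
# dwell times and the survival fit
# ---------------------------------------------------------------------------

@dataclass
class DwellTimeSample:
    """Observed state durations of one label, with right-censoring flags."""

    label: str
    durations: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise EstimationError("durations and censoring flags differ in length")
        if np.any(self.durations <= 0):
            raise EstimationError("non-positive dwell duration")

    @property
    def n(self) -> int:
        return len(self.durations)


@dataclass
class TauFit:
    """Exponential lifetime from the log-survival fit.

    ``tau`` in hours; ``intercept`` is the dimensionless offset c of
    f(t) = -(1/tau) t + c; the 99% confidence interval is obtained by
    propagating the 99% CI of the fitted slope (tau = -1/slope is monotone
    in the slope; an upper slope bound >= 0 yields an infinite upper tau
    bound).
    """

    tau: float
    intercept: float
    ci99_low: float
    ci99_high: float
    fit_range: tuple[float, float]
    n_states: int
    n_points: int

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise DegenerateFitError(f"tau must be > 0, got {self.tau}")
        if not (self.ci99_low <= self.tau <= self.ci99_high):
            raise EstimationError("tau outside its own confidence interval")


def collect_dwell_times(
    segments_by_cell: Mapping[str, Sequence[StateSegment]],
    censor_horizon: float = DEFAULT_CENSOR_HORIZON,
) -> dict[str, DwellTimeSample]:
    """Pool state durations over cells, applying the censor-horizon start rule.

    A segment enters the sample iff it starts at least ``censor_horizon``
    before the end of its cell's track.  Segments still ongoing at track end
    are kept with their observed duration and flagged censored; segments
    touching the track start are kept (the rule conditions only on the
    distance to the track end).
    """
    durations: dict[str, list[float]] = {RUN: [], REST: []}
    censored: dict[str, list[bool]] = {RUN: [], REST: []}
    for cell_id, segments in segments_by_cell.items():
        if not segments:
            continue
        track_end = segments[-1].end
        for seg in segments:
            if track_end - seg.start < censor_horizon:
                continue
            durations[seg.label].append(seg.duration)
            censored[seg.label].append(seg.ends_at_track_end)
    return {
        label: DwellTimeSample(label, np.array(durations[label]), np.array(censored[label]))
        for label in (RUN, REST)
    }


def survival_function(
    sample: DwellTimeSample, dt: float, horizon: float = DEFAULT_CENSOR_HORIZON
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival S(t) = #(T > t)/n on the grid t = 0, dt, ..., horizon."""
    if sample.n < 1:
        raise EstimationError(f"empty dwell-time sample for {sample.label}")
    t = np.arange(0.0, horizon + 0.5 * dt, dt)
    sorted_d = np.sort(sample.durations)
    s = 1.0 - np.searchsorted(sorted_d, t, side="right") / sample.n
    return t, s


def _logsurvival_slope(
    t: np.ndarray, s: np.ndarray, fit_range: tuple[float, float]
) -> tuple[float, float, float, int]:
    """Weighted LS slope/intercept of log S(t) on the fit range.

    Weights are inverse delta-method variances of log S under binomial
    counting, w ~ S/(1-S) (the shared 1/n factor cancels): deep-tail grid
    points, where log S rests on a handful of surviving states, carry
    little weight instead of dominating the fit.

    Returns (slope, intercept, slope_se, n_points).
    """
    mask = (t >= fit_range[0]) & (t <= fit_range[1]) & (s > 0)
    n_pts = int(mask.sum())
    if n_pts < 3:
        raise FitError(f"only {n_pts} grid points with S(t) > 0 inside {fit_range}")
    x = t[mask]
    y = np.log(s[mask])
    w = s[mask] / np.maximum(1.0 - s[mask], 1e-12)
    wsum = w.sum()
    xbar = np.sum(w * x) / wsum
    ybar = np.sum(w * y) / wsum
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sigma2 = np.sum(w * resid**2) / (n_pts - 2)
    slope_se = float(np.sqrt(sigma2 / sxx))
    return float(slope), float(intercept), slope_se, n_pts


def _tau_from_slope_ci(
    slope: float,
    intercept: float,
    slope_ci: tuple[float, float],
    fit_range: tuple[float, float],
    n_states: int,
    n_points: int,
) -> TauFit:
    if slope >= 0:
        raise DegenerateFitError(f"non-negative log-survival slope {slope:.3g}")
    slope_lo, slope_hi = slope_ci
    tau = -1.0 / slope
    ci_low = min(-1.0 / slope_lo, tau) if slope_lo < 0 else tau
    ci_high = max(-1.0 / slope_hi, tau) if slope_hi < 0 else np.inf
    return TauFit(
        tau=float(tau),
        intercept=float(intercept),
        ci99_low=float(ci_low),
        ci99_high=float(ci_high),
        fit_range=fit_range,
        n_states=n_states,
        n_points=n_points,
    )


def fit_tau(
    t: np.ndarray,
    s: np.ndarray,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    n_states: int = 0,
) -> TauFit:
    """Fit log S(t) = -(1/tau) t + c by weighted least squares on `fit_range`.

    Grid points with S(t) = 0 are dropped (log undefined); the remaining
    points are weighted by the inverse binomial variance of log S.  On exact
    log-linear input the fit reproduces tau to numerical precision for any
    weighting.  The 99% CI of the slope uses the t distribution with
    (n_points - 2) degrees of freedom and is propagated to tau through the
    monotone map tau = -1/slope; :func:`fit_tau_from_sample` replaces it
    with a resampling interval when the underlying dwell sample is at hand.

    Raises
    ------
    FitError
        Fewer than 3 usable grid points in the fit range.
    DegenerateFitError
        Non-negative fitted slope (tau undefined).
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    slope, intercept, slope_se, n_pts = _logsurvival_slope(t, s, fit_range)
    tcrit = stats.t.ppf(0.995, n_pts - 2)
    ci = (slope - tcrit * slope_se, slope + tcrit * slope_se)
    return _tau_from_slope_ci(slope, intercept, ci, fit_range, n_states, n_pts)


#: resamples for the bootstrap slope CI; fixed internal seed keeps outputs
#: deterministic for identical input
N_BOOTSTRAP = 200
_BOOTSTRAP_SEED = 1_234_567


def fit_tau_from_sample(
    sample: DwellTimeSample,
    dt: float,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    horizon: float = DEFAULT_CENSOR_HORIZON,
    ci_method: str = "bootstrap",
    n_boot: int = N_BOOTSTRAP,
) -> TauFit:
    """Empirical survival on the dt grid, then the log-linear fit.

    With ``ci_method="bootstrap"`` (default) the 99% CI of the slope is the
    percentile interval over resamples of the dwell sample, which reflects
    the true replicate-to-replicate variability of the estimator; the
    residual-based interval of :func:`fit_tau` ("analytic") treats the grid
    points of one empirical survival curve as independent observations and
    is far too narrow.
    """
    t, s = survival_function(sample, dt, horizon)
    if ci_method == "analytic":
        return fit_tau(t, s, fit_range, n_states=sample.n)
    if ci_method != "bootstrap":
        raise EstimationError(f"unknown ci_method {ci_method!r}")
    slope, intercept, _, n_pts = _logsurvival_slope(t, s, fit_range)
    rng = np.random.default_rng(_BOOTSTRAP_SEED)
    slopes = []
    n = sample.n
    grid = np.arange(0.0, horizon + 0.5 * dt, dt)
    for _ in range(n_boot):
        d = rng.choice(sample.durations, n, replace=True)
        sb = 1.0 - np.searchsorted(np.sort(d), grid, side="right") / n
        try:
            bslope, _, _, _ = _logsurvival_slope(grid, sb, fit_range)
        except FitError:
            continue
        slopes.append(bslope)
    if len(slopes) < max(20, n_boot // 2):
        logger.warning(
            "tau bootstrap unstable (%d/%d usable resamples); analytic CI used",
            len(slopes),
            n_boot,
        )
        return fit_tau(t, s, fit_range, n_states=sample.n)
    ci = tuple(np.quantile(slopes, [0.005, 0.995]))
    return _tau_from_slope_ci(slope, intercept, ci, fit_range, sample.n, n_pts)


# ---------------------------------------------------------------------------
# per-cell parameters
# ---------------------------------------------------------------------------

def run_velocity(vel: VelocitySeries, segments: Sequence[StateSegment]) -> float:
    """Per-cell run velocity: mean |v_tang| over RUN-state frames.

    Returns NaN for a cell with no RUN frames (the value is undefined; such
    cells are excluded from the population mean and counted toward the
    immobile fraction by the callers).
    """
    mask = frame_labels(list(segments), len(vel.v_tang))
    if not mask.any():
        return float("nan")
    return float(np.mean(np.abs(vel.v_tang[mask])))


def run_fraction(segments: Sequence[StateSegment]) -> float:
    """Per-cell P_run: time in RUN segments divided by the track duration."""
    total = segments[-1].end - segments[0].start
    run_time = sum(seg.duration for seg in segments if seg.label == RUN)
    return run_time / total


def persistence_q(traj: Trajectory) -> float:
    """Per-cell persistence: positional range over total path length.

    q = (max phi - min phi) / sum_i |phi[i+1] - phi[i]|; 1 for strictly
    monotone (ballistic) trajectories, near 0 for back-and-forth wiggling.
    Returns NaN when the path length is zero (cell immobile to numerical
    precision).
    """
    path = float(np.sum(np.abs(np.diff(traj.phi))))
    if path == 0.0:
        return float("nan")
    return float((traj.phi.max() - traj.phi.min()) / path)


def immobile_fraction(segments_by_cell: Mapping[str, Sequence[StateSegment]]) -> float:
    """Fraction of cells whose whole track is a single REST segment."""
    if not segments_by_cell:
        raise EstimationError("no cells")
    n_immobile = sum(
        1
        for segs in segments_by_cell.values()
        if len(segs) == 1 and segs[0].label == REST
    )
    return n_immobile / len(segments_by_cell)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return float("nan"), float("nan")
    se = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(np.mean(values)), se


# ---------------------------------------------------------------------------
# population fingerprint
# ---------------------------------------------------------------------------

@dataclass
class MotilityFingerprint:
    """Population-level five-parameter motility fingerprint.

    v_run, p_run and q carry standard errors over cells; the taus carry the
    99% CI of the survival fit.  A tau that could not be fitted is None, with
    the reason in ``diagnostics``.
    """

    v_run: float
    v_run_se: float
    tau_run: TauFit | None
    tau_rest: TauFit | None
    p_run: float
    p_run_se: float
    q: float
    q_se: float
    n_cells: int
    immobile_fraction: float
    diagnostics: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "v_run": {
                "value": self.v_run,
                "error_low": self.v_run_se,
                "error_high": self.v_run_se,
                "n": self.n_cells,
            },
            "p_run": {
                "value": self.p_run,
                "error_low": self.p_run_se,
                "error_high": self.p_run_se,
                "n": self.n_cells,
            },
            "q": {
                "value": self.q,
                "error_low": self.q_se,
                "error_high": self.q_se,
                "n": self.n_cells,
            },
            "immobile_fraction": {
                "value": self.immobile_fraction,
                "error_low": 0.0,
                "error_high": 0.0,
                "n": self.n_cells,
            },
        }
        for name, fit in (("tau_run", self.tau_run), ("tau_rest", self.tau_rest)):
            if fit is None:
                out[name] = {"value": None, "error_low": None, "error_high": None, "n": 0}
            else:
                out[name] = {
                    "value": fit.tau,
                    "error_low": fit.tau - fit.ci99_low,
                    "error_high": fit.ci99_high - fit.tau,
                    "n": fit.n_states,
                }
        if self.diagnostics:
            out["diagnostics"] = dict(self.diagnostics)
        return out


@dataclass
class FingerprintResult:
    """Fingerprint plus the per-cell table and segments it was computed from."""

    fingerprint: MotilityFingerprint
    per_cell: pd.DataFrame
    segments: dict[str, list[StateSegment]]
    velocities: dict[str, VelocitySeries]


def fingerprint(
    collection: TrajectoryCollection,
    seg_params: SegmentationParams | None = None,
    censor_horizon: float = DEFAULT_CENSOR_HORIZON,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    segmenter: Segmenter = segment_states,
    pool_frames: bool = False,
) -> FingerprintResult:
    """Full pipeline: velocities -> segmentation -> all five motility parameters.

    Parameters
    ----------
    pool_frames : bool
        When True the population v_run pools all RUN frames of all cells
        instead of averaging per-cell means (each cell weighted equally,
        the default).

    A failed tau fit is reported as a missing value with a diagnostic message
    rather than aborting the remaining parameters.
    """
    if len(collection) < 2:
        raise EstimationError("need at least 2 cells for a population fingerprint")
    seg_params = seg_params or SegmentationParams()

    rows = []
    segments_by_cell: dict[str, list[StateSegment]] = {}
    velocities: dict[str, VelocitySeries] = {}
    pooled_abs_v: list[np.ndarray] = []
    for traj in collection:
        vel = tangential_velocity(traj, collection.geometry, seg_params.smooth_window)
        segs = segmenter(vel, seg_params)
        segments_by_cell[traj.cell_id] = segs
        velocities[traj.cell_id] = vel
        mask = frame_labels(segs, len(vel.v_tang))
        if mask.any():
            pooled_abs_v.append(np.abs(vel.v_tang[mask]))
        rows.append(
            {
                "cell_id": traj.cell_id,
                "v_run": run_velocity(vel, segs),
                "p_run": run_fraction(segs),
                "q": persistence_q(traj),
                "n_run_states": sum(1 for s in segs if s.label == RUN),
                "n_rest_states": sum(1 for s in segs if s.label == REST),
                "immobile": len(segs) == 1 and segs[0].label == REST,
            }
        )
    per_cell = pd.DataFrame(rows)

    n_undefined_q = int(per_cell["q"].isna().sum())
    if n_undefined_q:
        logger.info("%d cells with zero path length excluded from q", n_undefined_q)

    if pool_frames and pooled_abs_v:
        pooled = np.concatenate(pooled_abs_v)
        v_run_pop = float(pooled.mean())
        v_run_se = float(pooled.std(ddof=1) / np.sqrt(len(pooled)))
    else:
        v_run_pop, v_run_se = _mean_se(per_cell["v_run"].to_numpy())
    p_run_pop, p_run_se = _mean_se(per_cell["p_run"].to_numpy())
    q_pop, q_se = _mean_se(per_cell["q"].to_numpy())

    samples = collect_dwell_times(segments_by_cell, censor_horizon)
    diagnostics: dict[str, str] = {}
    fits: dict[str, TauFit | None] = {}
    for label in (RUN, REST):
        try:
            fits[label] = fit_tau_from_sample(
                samples[label], collection.dt, fit_range, censor_horizon
            )
        except EstimationError as exc:
            fits[label] = None
            diagnostics[f"tau_{label.lower()}"] = str(exc)
            logger.warning("tau_%s fit failed: %s", label.lower(), exc)

    fp = MotilityFingerprint(
        v_run=v_run_pop,
        v_run_se=v_run_se,
        tau_run=fits[RUN],
        tau_rest=fits[REST],
        p_run=p_run_pop,
        p_run_se=p_run_se,
        q=q_pop,
        q_se=q_se,
        n_cells=len(collection),
        immobile_fraction=immobile_fraction(segments_by_cell),
        diagnostics=diagnostics,
    )
    return FingerprintResult(fp, per_cell, segments_by_cell, velocities)


def spider_table(
    fingerprints: Mapping[str, MotilityFingerprint], reference: str
) -> pd.DataFrame:
    """Per-parameter values normalized to a named reference condition.

    Produces the long-format table behind a radar ("spider") plot: one row
    per (condition, parameter) with the raw value and the value divided by
    the reference condition's value.
    """
    if reference not in fingerprints:
        raise EstimationError(f"reference condition {reference!r} not among fingerprints")
    params = ("v_run", "tau_run", "tau_rest", "p_run", "q")

    def value(fp: MotilityFingerprint, name: str) -> float:
        if name in ("tau_run", "tau_rest"):
            fit = getattr(fp, name)
            return float("nan") if fit is None else fit.tau
        return getattr(fp, name)

    ref = fingerprints[reference]
    rows = []
    for cond, fp in fingerprints.items():
        for name in params:
            v = value(fp, name)
            r = value(ref, name)
            rows.append(
                {
                    "condition": cond,
                    "parameter": name,
                    "value": v,
                    "normalized": v / r if r else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    """Welch (or pooled) two-sided two-sample t-test on per-cell values."""

    parameter: str
    mean_a: float
    mean_b: float
    diff: float  # mean_a - mean_b
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


@dataclass
class TauComparison:
    """Comparison of two population-level tau fits via their 99% CIs."""

    parameter: str
    tau_a: float | None
    tau_b: float | None
    diff: float | None
    ci_overlap: bool | None


def compare_fingerprints(
    per_cell_a: pd.DataFrame,
    per_cell_b: pd.DataFrame,
    fingerprint_a: MotilityFingerprint | None = None,
    fingerprint_b: MotilityFingerprint | None = None,
    welch: bool = True,
) -> dict[str, TTestResult | TauComparison]:
    """Per-parameter comparison of two conditions.

    v_run, p_run and q are compared by a two-sided two-sample t-test on
    per-cell values (Welch variant by default); the taus, being single
    population-level fits, are compared by non-overlap of their 99% CIs.
    """
    results: dict[str, TTestResult | TauComparison] = {}
    for param in ("v_run", "p_run", "q"):
        a = per_cell_a[param].to_numpy(dtype=float)
        b = per_cell_b[param].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise EstimationError(f"{param}: need >= 2 defined values per condition")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise EstimationError(f"{param}: degenerate (zero) variance in both groups")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        results[param] = TTestResult(
            parameter=param,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            diff=float(a.mean() - b.mean()),
            statistic=float(res.statistic),
            pvalue=float(res.pvalue),
            n_a=len(a),
            n_b=len(b),
        )
    if fingerprint_a is not None and fingerprint_b is not None:
        for name in ("tau_run", "tau_rest"):
            fa: TauFit | None = getattr(fingerprint_a, name)
            fb: TauFit | None = getattr(fingerprint_b, name)
            if fa is None or fb is None:
                results[name] = TauComparison(name, None, None, None, None)
            else:
                overlap = fa.ci99_low <= fb.ci99_high and fb.ci99_low <= fa.ci99_high
                results[name] = TauComparison(
                    name, fa.tau, fb.tau, fa.tau - fb.tau, bool(overlap)
                )
    return results
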