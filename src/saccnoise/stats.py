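"""Trajectory statistics: detection, binning, variance/covariance/correlation
trajectories, amplitude–duration statistics and the proportionality index.

Two normalization conventions are supported when pooling trials:

``per_trial``
    Each trial's detected [onset, offset] interval is linearly time-warped
    onto a common 100-sample axis (the treatment applied to recorded data,
    where absolute timing is uncertain).

``fixed_window``
    All trials are sampled at the same absolute times over a common window
    [t0, t0 + D].  This estimates the variance of eye position *at fixed
    time*, which is the quantity the analytic noise propagation predicts, so
    it is the estimator used whenever simulations are validated against the
    theory.  Per-trial warping mixes duration jitter into the position
    variance and estimates a slightly different quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .dynamics import gaussian_lowpass

if TYPE_CHECKING:  # pragma: no cover
    from .synth import TrialEnsemble

__all__ = [
    "Detection",
    "TrajectoryStatistics",
    "AmplitudeDurationStats",
    "detect_saccade",
    "detect_matrix",
    "bin_by_motor_error",
    "normalize_and_resample",
    "warp_trials",
    "variance_standard_errors",
    "correlation_trajectory",
    "amplitude_duration_stats",
    "main_sequence_at_fixed_amplitude",
    "proportionality_index",
    "empirical_family",
]


@dataclass(frozen=True)
class Detection:
    """Threshold detection result for one trial (indices into the trace)."""

    onset: int
    offset: int
    amplitude: float
    duration: float
    peak_velocity: float
    found: bool = True


@dataclass
class TrajectoryStatistics:
    """Per-condition trajectory statistics on a normalized 100-sample axis."""

    t_norm: np.ndarray          # normalized time, [0, 1]
    y_bar: np.ndarray           # mean trajectory (deg)
    var_y: np.ndarray           # variance trajectory (deg^2)
    cov_ye: np.ndarray          # covariance with end position (deg^2)
    A_bar: float                # mean amplitude (deg)
    D_bar: float                # mean duration (s)
    n_trials: int
    mode: str = "per_trial"

    @property
    def rho_ye(self) -> np.ndarray:
        """Correlation trajectory (Pearson r of y(t) with y(end)); masked
        (NaN) where the variance vanishes."""
        denom = np.sqrt(self.var_y * self.var_y[-1])
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, self.cov_ye / np.where(denom > 0, denom, 1.0), np.nan)
        return rho


@dataclass(frozen=True)
class AmplitudeDurationStats:
    """Inter-trial amplitude/duration statistics of one saccade class."""

    var_tdur_ms2: float
    var_amp: float
    cc_tdur_amp: float
    alpha: float                # deg/ms, OLS slope of amplitude on duration
    alpha2_var_tdur: float      # deg^2, main-sequence-implied amplitude variance
    n_trials: int


def detect_saccade(
    position: np.ndarray,
    rate: float,
    vel_floor: float = 30.0,
    filter_hz: float | None = 100.0,
) -> Detection:
    """Detect one saccade by the 10%-of-peak-velocity criterion.

    Onset is the first sample where |velocity| rises above 10% of the peak;
    offset is the first sample after the peak where it falls below again.
    Returns ``found=False`` when no sample exceeds ``vel_floor`` (deg/s).
    """
    det = detect_matrix(np.asarray(position, float)[np.newaxis, :], rate, vel_floor, filter_hz)
    return Detection(
        onset=int(det["onset"][0]),
        offset=int(det["offset"][0]),
        amplitude=float(det["amplitude"][0]),
        duration=float(det["duration"][0]),
        peak_velocity=float(det["peak_velocity"][0]),
        found=bool(det["found"][0]),
    )


def detect_matrix(
    Y: np.ndarray,
    rate: float,
    vel_floor: float = 30.0,
    filter_hz: float | None = 100.0,
) -> dict:
    """Vectorized threshold detection for a (n_trials, n_samples) matrix."""
    dt = 1.0 / rate
    Yf = gaussian_lowpass(Y, dt, filter_hz, axis=1) if filter_hz else Y
    V = np.gradient(Yf, dt, axis=1)
    speed = np.abs(V)
    ipk = np.argmax(speed, axis=1)
    vpk = speed[np.arange(len(Y)), ipk]
    found = vpk >= vel_floor
    thr = 0.1 * vpk
    above = speed >= thr[:, None]
    n = Y.shape[1]
    idx = np.arange(n)[None, :]
    rows = np.arange(len(Y))
    # onset: first above-threshold sample
    onset = np.argmax(above, axis=1)
    # offset: last above-threshold sample before the first post-peak dip
    after_peak_below = (~above) & (idx > ipk[:, None])
    has_off = after_peak_below.any(axis=1)
    offset = np.where(has_off, np.argmax(after_peak_below, axis=1) - 1, n - 1)
    offset = np.maximum(offset, onset + 1)
    # sub-sample refinement of the threshold crossings (linear interpolation
    # of the speed trace between the bracketing samples)
    t = np.arange(n) * dt
    onset_time = t[onset].astype(float)
    offset_time = t[offset].astype(float)
    j = onset
    can = j > 0
    s0 = speed[rows, np.maximum(j - 1, 0)]
    s1 = speed[rows, j]
    frac = np.where((s1 - s0) > 0, (thr - s0) / np.where(s1 != s0, s1 - s0, 1.0), 1.0)
    onset_time = np.where(can & found, t[np.maximum(j - 1, 0)] + np.clip(frac, 0, 1) * dt, onset_time)
    j2 = np.minimum(offset + 1, n - 1)
    s0 = speed[rows, offset]
    s1 = speed[rows, j2]
    frac = np.where((s0 - s1) > 0, (s0 - thr) / np.where(s0 != s1, s0 - s1, 1.0), 0.0)
    offset_time = np.where((j2 > offset) & found, t[offset] + np.clip(frac, 0, 1) * dt, offset_time)
    # amplitude from sub-sample positions of the raw trace
    y_on = np.array([np.interp(onset_time[i], t, Y[i]) for i in rows])
    y_off = np.array([np.interp(offset_time[i], t, Y[i]) for i in rows])
    return {
        "onset": onset,
        "offset": offset,
        "onset_time": onset_time,
        "offset_time": offset_time,
        "amplitude": y_off - y_on,
        "duration": offset_time - onset_time,
        "peak_velocity": vpk,
        "peak_index": ipk,
        "found": found,
    }


def bin_by_motor_error(
    ensemble: "TrialEnsemble",
    centers: tuple[float, ...] = (-20.0, -15.0, -10.0, -5.0, 5.0, 10.0, 15.0, 20.0),
    half_width: float = 2.5,
) -> dict[float, "TrialEnsemble"]:
    """Sort trials into motor-error classes [center−w, center+w).

    Trials outside every class are dropped (count retrievable by comparing
    sizes).  Empty classes are omitted from the result.
    """
    out: dict[float, TrialEnsemble] = {}
    me = ensemble.motor_errors
    for c in centers:
        mask = (me >= c - half_width) & (me < c + half_width)
        if mask.any():
            out[c] = ensemble.subset(np.flatnonzero(mask))
    return out


def warp_trials(
    ensemble: "TrialEnsemble",
    n_samples: int = 100,
    mode: str = "per_trial",
    window: tuple[float, float] | None = None,
    windows: tuple[np.ndarray, np.ndarray] | None = None,
    interp: str = "linear",
) -> tuple[np.ndarray, float]:
    """Resample every trial onto a common ``n_samples`` axis.

    Returns ``(W, D_bar)`` where ``W`` is the (n_trials, n_samples) matrix of
    onset-referenced positions and ``D_bar`` the window duration.  See
    :func:`normalize_and_resample` for the meaning of the arguments.
    """
    from scipy.interpolate import CubicSpline

    if interp not in ("linear", "cubic"):
        raise ValueError("interp must be 'linear' or 'cubic'")
    Y = ensemble.positions
    t = ensemble.time

    def _interpolator(yi):
        if interp == "cubic":
            return CubicSpline(t, yi)
        return lambda x: np.interp(x, t, yi)

    if windows is not None:
        t_on = np.broadcast_to(np.asarray(windows[0], float), (len(Y),))
        t_off = np.broadcast_to(np.asarray(windows[1], float), (len(Y),))
    else:
        t_on, t_off = ensemble.onset_times, ensemble.offset_times
    valid = t_off > t_on
    if not valid.all():
        Y, t_on, t_off = Y[valid], t_on[valid], t_off[valid]
    n_tr = len(Y)
    warped = np.empty((n_tr, n_samples))
    if mode == "per_trial":
        s = np.linspace(0.0, 1.0, n_samples)
        for i in range(n_tr):
            f = _interpolator(Y[i])
            warped[i] = f(t_on[i] + s * (t_off[i] - t_on[i])) - f(t_on[i])
        D_bar = float(np.mean(t_off - t_on))
    elif mode == "fixed_window":
        if window is None:
            t0 = float(np.mean(t_on))
            D_bar = float(np.mean(t_off - t_on))
        else:
            t0, D_bar = float(window[0]), float(window[1])
        ts = t0 + np.linspace(0.0, 1.0, n_samples) * D_bar
        for i in range(n_tr):
            f = _interpolator(Y[i])
            warped[i] = f(ts) - f(t0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return warped, D_bar


def variance_standard_errors(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment-based standard errors of the sample variance trajectory and of
    the covariance-with-endpoint trajectory of a warped-trial matrix.

    Uses the empirical fourth moments, so heavy-tailed samples (e.g. strong
    multiplicative feedback noise) get correspondingly wide error bars.
    """
    n = len(W)
    dev = W - W.mean(axis=0)
    e = dev[:, -1]
    se_var = np.sqrt(np.maximum((dev**4).mean(0) - ((dev**2).mean(0)) ** 2, 0.0) / n)
    se_cov = np.sqrt(
        np.maximum(((dev**2) * (e**2)[:, None]).mean(0) - ((dev * e[:, None]).mean(0)) ** 2, 0.0) / n
    )
    return se_var, se_cov


def normalize_and_resample(
    ensemble: "TrialEnsemble",
    n_samples: int = 100,
    mode: str = "per_trial",
    window: tuple[float, float] | None = None,
    windows: tuple[np.ndarray, np.ndarray] | None = None,
    interp: str = "linear",
) -> TrajectoryStatistics:
    """Pool trials into mean/variance/covariance trajectories.

    per_trial mode warps each trial's [onset, offset] onto ``n_samples``
    equidistant points; fixed_window samples every trial at the same
    ``n_samples`` absolute times spanning ``window = (t_start, duration)``
    (defaults to mean onset time and mean detected duration).  ``windows``
    optionally overrides the detected per-trial (onset, offset) times with
    externally known ones — simulation-validation harnesses pass the
    generator's true movement windows here so that estimator noise from
    threshold detection does not contaminate the comparison.  ``interp``
    selects the resampling rule: "linear" (default; appropriate for
    stochastic traces, where spline overshoot would inflate the variance)
    or "cubic" (for smooth traces, where linear interpolation leaves a
    measurable error floor).  The end position is the last resampled point
    of each trial, so the covariance trajectory terminates at the variance
    and the correlation at exactly 1.
    """
    if ensemble.n_trials < 2:
        raise ValueError("need at least 2 trials for trajectory statistics")
    warped, D_bar = warp_trials(ensemble, n_samples, mode, window, windows, interp)
    n_tr = len(warped)
    end = warped[:, -1]
    y_bar = warped.mean(axis=0)
    var_y = warped.var(axis=0, ddof=1)
    cov_ye = ((warped - y_bar) * (end - end.mean())[:, None]).sum(axis=0) / (n_tr - 1)
    valid_amp = ensemble.offset_times > ensemble.onset_times
    return TrajectoryStatistics(
        t_norm=np.linspace(0.0, 1.0, n_samples),
        y_bar=y_bar,
        var_y=var_y,
        cov_ye=cov_ye,
        A_bar=float(np.mean(ensemble.amplitudes[valid_amp])),
        D_bar=D_bar,
        n_trials=n_tr,
        mode=mode,
    )


def correlation_trajectory(stats: TrajectoryStatistics, threshold: float = 0.9) -> tuple[np.ndarray, float]:
    """Correlation trajectory and ``P_ρ`` = first crossing of ``threshold``
    as a percentage of the saccade duration (linear sub-sample
    interpolation).  Returns (rho, P) with P = NaN when never crossed."""
    rho = stats.rho_ye
    ok = np.isfinite(rho)
    above = ok & (rho >= threshold)
    if not above.any():
        return rho, float("nan")
    j = int(np.argmax(above))
    if j == 0 or not ok[j - 1]:
        t_cross = stats.t_norm[j]
    else:
        r0, r1 = rho[j - 1], rho[j]
        frac = (threshold - r0) / (r1 - r0)
        t_cross = stats.t_norm[j - 1] + frac * (stats.t_norm[j] - stats.t_norm[j - 1])
    return rho, float(100.0 * t_cross)


def amplitude_duration_stats(
    ensemble: "TrialEnsemble",
    alpha: float | None = None,
) -> AmplitudeDurationStats:
    """var(duration), var(amplitude), their correlation, and the implied
    main-sequence amplitude variance α²·var_TDur.

    ``alpha`` (deg/ms) should be the main-sequence slope estimated across
    the full amplitude range of a session (OLS of amplitude on duration);
    within a single motor-error class the OLS slope is attenuated by
    duration jitter unrelated to amplitude, so pass the session estimate
    when comparing var_Amp with α²·var_TDur.  When omitted, the slope is
    estimated from the given ensemble itself.
    """
    if ensemble.n_trials < 3:
        raise ValueError("need at least 3 trials")
    dur_ms = ensemble.durations * 1e3
    amp = ensemble.amplitudes
    var_tdur = float(np.var(dur_ms, ddof=1))
    var_amp = float(np.var(amp, ddof=1))
    if var_tdur == 0:
        raise ValueError("zero duration variance: correlation and alpha undefined")
    cc = float(np.corrcoef(dur_ms, amp)[0, 1])
    if alpha is None:
        alpha = float(np.polyfit(dur_ms, amp, 1)[0])
    return AmplitudeDurationStats(
        var_tdur_ms2=var_tdur,
        var_amp=var_amp,
        cc_tdur_amp=cc,
        alpha=alpha,
        alpha2_var_tdur=alpha**2 * var_tdur,
        n_trials=ensemble.n_trials,
    )


def main_sequence_at_fixed_amplitude(ensemble: "TrialEnsemble", A0: float = 10.0) -> dict:
    """Main-sequence values interpolated at amplitude ``A0``.

    Duration and deceleration duration are fitted linearly in amplitude,
    peak velocity with a saturating power law v = a·A^b (log–log OLS),
    across the ensemble's full amplitude range.  No extrapolation.
    """
    amp = ensemble.amplitudes
    if not (amp.min() <= A0 <= amp.max()):
        raise ValueError(f"A0={A0} outside observed amplitude range "
                         f"[{amp.min():.2f}, {amp.max():.2f}]; refusing to extrapolate")
    dur_ms = ensemble.durations * 1e3
    vpk = ensemble.peak_velocities
    decel_ms = ensemble.decel_durations * 1e3
    dur_fit = np.polyfit(amp, dur_ms, 1)
    dec_fit = np.polyfit(amp, decel_ms, 1)
    pw = np.polyfit(np.log(amp), np.log(vpk), 1)
    return {
        "amplitude": A0,
        "peak_velocity": float(np.exp(np.polyval(pw, np.log(A0)))),
        "total_duration_ms": float(np.polyval(dur_fit, A0)),
        "decel_duration_ms": float(np.polyval(dec_fit, A0)),
    }


def proportionality_index(vectors: np.ndarray, standardize: bool = True) -> float:
    """Proportionality index of multi-component effect vectors.

    ``F_prop`` is the fraction of the (origin-referenced) total variance
    captured by projecting the data onto the axis through the origin and
    the sample mean; ``I_prop = (F_prop − 1/n)/(1 − 1/n)`` rescales so that
    a spherical cloud at the origin scores 0 and perfectly proportional
    vectors score 1.  Components are standardized by their across-subject
    standard deviation before projection.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a (n_subjects, n_components) array with >= 2 rows")
    n = X.shape[1]
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero across-subject SD in a component")
        X = X / sd
    mean = X.mean(axis=0)
    dev = X - mean
    total = np.sum(dev**2)
    if total == 0:
        raise ValueError("zero total variance: proportionality undefined")
    norm = np.linalg.norm(mean)
    if norm == 0:
        return (0.0 - 1.0 / n) / (1.0 - 1.0 / n)
    u = mean / norm
    # for an isotropic cloud at the origin the axis (a function of the mean
    # only) is independent of the deviations, so E[f_prop] = 1/n exactly
    f_prop = np.sum((dev @ u) ** 2) / total
    return float((f_prop - 1.0 / n) / (1.0 - 1.0 / n))


def empirical_family(
    session: "TrialEnsemble",
    A_bar: float,
    plant=None,
    delta: float = 5.0,
    n_norm: int = 100,
    step: float = 5e-4,
):
    """Estimate a mean-trajectory family from data alone.

    The two flanking members are the averages of the per-trial-normalized
    trajectories of all saccades with amplitudes in [Ā−Δ, Ā] and [Ā, Ā+Δ]
    (a session spanning several target eccentricities is needed for these
    ranges to be well populated).  The difference quotient divides by the
    *measured* separation of the two groups' mean amplitudes, which keeps
    the amplitude sensitivity exactly 1 at movement end even when the
    amplitude distribution does not fill the nominal bins.  The center
    member is the fixed-window average of saccades within Δ/2 of Ā; its
    internal commands are recovered by numerical inversion.
    """
    from .propagation import MeanFamily

    A = session.amplitudes
    masks = {
        "plus": (A >= A_bar) & (A < A_bar + delta),
        "minus": (A >= A_bar - delta) & (A < A_bar),
        "center": np.abs(A - A_bar) <= delta / 2.0,
    }
    members = {}
    mean_amp = {}
    for key in ("plus", "minus"):
        idx = np.flatnonzero(masks[key])
        if len(idx) < 10:
            raise ValueError(f"too few trials ({len(idx)}) in the {key} amplitude range")
        W, _ = warp_trials(session.subset(idx), n_samples=n_norm, mode="per_trial")
        members[key] = W.mean(axis=0)
        mean_amp[key] = float(np.mean(A[idx]))
    delta_eff = mean_amp["plus"] - mean_amp["minus"]
    if delta_eff <= 0:
        raise ValueError("flanking amplitude groups are not separated")
    idx_c = np.flatnonzero(masks["center"])
    if len(idx_c) < 10:
        raise ValueError("too few trials near the center amplitude")
    center = session.subset(idx_c)
    t0 = float(np.mean(center.onset_times))
    D_bar = float(np.mean(center.offset_times - center.onset_times))
    Wc, _ = warp_trials(center, n_samples=200, mode="fixed_window", window=(t0, D_bar))
    t_axis = np.linspace(0.0, D_bar, 200)
    return MeanFamily.from_trajectories(
        t=t_axis,
        y_bar=Wc.mean(axis=0),
        y_plus=members["plus"],
        y_minus=members["minus"],
        A_bar=float(A_bar),
        D_bar=D_bar,
        plant=plant,
        delta=delta_eff,
        step=step,
        n_norm=n_norm,
    )
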