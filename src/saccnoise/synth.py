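"""Monte-Carlo generator of noisy saccade trial ensembles.

Trials realize the generative model behind the analytic noise propagation:

* planning noise — the planned amplitude of each trial is drawn from
  ``Normal(Ā, k_A²·Ā²)`` and the trial follows the corresponding member of
  the main-sequence trajectory family;
* PBN noise — Gaussian white noise with SD ``k_PBN·|C2(t)|/√step`` injected
  at the premotor-burst output *inside* the delayed-integrator feedback
  loop;
* ON noise — Gaussian white noise with SD ``k_ON·|C3(t)|/√step`` added to
  the oculomotor command downstream of the loop.

Both signal-dependent noises scale with the instantaneous *noisy* command,
evaluated just before the current sample's own noise is added (the
self-referential scaling the analytic power-density recursion assumes).
The model is linear, so the mean path and the noise response superpose; the
noise response is propagated through the same discrete-time loop recursion,
pulse-step rule, and plant unit-sample convolution that the analytic
predictions use, making simulation and theory agree to sampling error at
matched step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

from .dynamics import LoopParameters, PlantParameters, TimeGrid, plant_impulse_response
from .profiles import MainSequenceModel
from .stats import detect_matrix

__all__ = [
    "NoiseCoefficients",
    "ConditionConfig",
    "SaccadeTrace",
    "TrialEnsemble",
    "PRESETS",
    "condition_preset",
    "mean_trajectory",
    "mean_controls",
    "simulate_trial",
    "generate_ensemble",
    "generate_session",
]


@dataclass(frozen=True)
class NoiseCoefficients:
    """Dimensionless noise strengths of the three sources."""

    k_A: float = 0.0
    k_ON: float = 0.0
    k_PBN: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_A, self.k_ON, self.k_PBN) < 0:
            raise ValueError("noise coefficients must be >= 0")


@dataclass(frozen=True)
class ConditionConfig:
    """Everything defining one experimental condition's generative model."""

    name: str = "custom"
    A_bar: float = 10.0
    noise: NoiseCoefficients = field(default_factory=NoiseCoefficients)
    loop: LoopParameters = field(default_factory=LoopParameters)
    plant: PlantParameters = field(default_factory=PlantParameters)
    main_sequence: MainSequenceModel = field(default_factory=MainSequenceModel)
    motor_error_center: float = 10.0
    motor_error_sd: float = 1.0
    motor_error_bounds: tuple[float, float] = (8.5, 12.5)
    step: float = 5e-4            # simulation step (s)
    output_rate: float = 1000.0   # trace sampling rate (Hz)
    post_margin: float = 0.040    # settle time simulated past movement end (s)


def _preset_ms(vpeak: float, dur_ms: float, decel_ms: float, alpha: float) -> MainSequenceModel:
    return MainSequenceModel(
        A_ref=10.0,
        D_ref=dur_ms * 1e-3,
        alpha=alpha,
        decel_fraction=decel_ms / dur_ms,
        vpeak_ref=vpeak,
    )


#: Condition presets; parameters follow the group means of the five-macaque
#: cFN-inactivation reference dataset (see :mod:`saccnoise.datasets`).
PRESETS: dict[str, ConditionConfig] = {
    "control": ConditionConfig(
        name="control",
        A_bar=10.1,
        noise=NoiseCoefficients(k_A=0.106, k_ON=0.0, k_PBN=0.028),
        loop=LoopParameters(g=240.0),
        main_sequence=_preset_ms(429.6, 40.0, 22.0, 0.66),
    ),
    "ipsiversive_cFN": ConditionConfig(
        name="ipsiversive_cFN",
        A_bar=18.1,
        noise=NoiseCoefficients(k_A=0.175, k_ON=0.0, k_PBN=0.029),
        loop=LoopParameters(g=94.0),
        main_sequence=_preset_ms(343.6, 52.6, 33.5, 0.56),
    ),
    "contraversive_cFN": ConditionConfig(
        name="contraversive_cFN",
        A_bar=7.5,
        noise=NoiseCoefficients(k_A=0.183, k_ON=0.0, k_PBN=0.042),
        loop=LoopParameters(g=208.0),
        main_sequence=_preset_ms(290.8, 65.0, 42.8, 0.37),
    ),
}


def condition_preset(name: str, **overrides) -> ConditionConfig:
    """Look up a named preset, optionally overriding fields."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class SaccadeTrace:
    """One trial's eye-position time series and detected landmarks."""

    time: np.ndarray
    position: np.ndarray
    onset: int
    offset: int
    amplitude: float
    duration: float
    motor_error: float
    rate: float
    planned_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("positions must be finite")


@dataclass
class TrialEnsemble:
    """A homogeneous set of trials from one condition (array-first storage)."""

    time: np.ndarray                 # (T,)
    positions: np.ndarray            # (n_trials, T)
    motor_errors: np.ndarray         # (n_trials,)
    planned_amplitudes: np.ndarray   # (n_trials,)
    onsets: np.ndarray               # (n_trials,) indices
    offsets: np.ndarray
    onset_times: np.ndarray          # (n_trials,) sub-sample times (s)
    offset_times: np.ndarray
    amplitudes: np.ndarray
    durations: np.ndarray            # s
    peak_velocities: np.ndarray
    peak_indices: np.ndarray
    condition: str = "custom"
    config: ConditionConfig | None = None
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.positions)

    @property
    def rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def decel_durations(self) -> np.ndarray:
        return self.offset_times - self.peak_indices / self.rate

    def subset(self, idx: np.ndarray) -> "TrialEnsemble":
        return TrialEnsemble(
            time=self.time,
            positions=self.positions[idx],
            motor_errors=self.motor_errors[idx],
            planned_amplitudes=self.planned_amplitudes[idx],
            onsets=self.onsets[idx],
            offsets=self.offsets[idx],
            onset_times=self.onset_times[idx],
            offset_times=self.offset_times[idx],
            amplitudes=self.amplitudes[idx],
            durations=self.durations[idx],
            peak_velocities=self.peak_velocities[idx],
            peak_indices=self.peak_indices[idx],
            condition=self.condition,
            config=self.config,
            seed=self.seed,
        )

    def traces(self) -> Iterator[SaccadeTrace]:
        for i in range(self.n_trials):
            yield SaccadeTrace(
                time=self.time,
                position=self.positions[i],
                onset=int(self.onsets[i]),
                offset=int(self.offsets[i]),
                amplitude=float(self.amplitudes[i]),
                duration=float(self.durations[i]),
                motor_error=float(self.motor_errors[i]),
                rate=self.rate,
                planned_amplitude=float(self.planned_amplitudes[i]),
            )


def mean_trajectory(A: float, ms: MainSequenceModel, grid: TimeGrid) -> np.ndarray:
    """Mean (noise-free) eye-position trace for planned amplitude ``A`` on
    ``grid``; rises smoothly from 0 to ``A`` over ``D(A)`` and then holds."""
    return ms.position(grid.times, float(A))


def mean_controls(A: float, ms: MainSequenceModel, plant: PlantParameters, grid: TimeGrid):
    """Exact internal commands (C̄2, C̄3) of one family member.

    Uses the profile's closed-form velocity derivatives in the plant
    inversion ``C2 = τ2τ3 v̈ + (τ2+τ3) v̇ + v`` and the identity
    ``∫C2 = τ2τ3 v̇ + (τ2+τ3) v + y``, avoiding numerical differentiation.
    """
    t = grid.times
    v, vd, vdd = ms.velocity_derivatives(t, float(A))
    y = cumulative_trapezoid(v, t, initial=0.0)
    C2 = plant.tau2 * plant.tau3 * vdd + (plant.tau2 + plant.tau3) * vd + v
    int_C2 = plant.tau2 * plant.tau3 * vd + (plant.tau2 + plant.tau3) * v + y
    C3 = plant.tau1 * C2 + int_C2
    return C2, C3, y


def _simulate_noise_matrix(
    C2_bar: np.ndarray,
    C3_bar: np.ndarray,
    nc: NoiseCoefficients,
    plant: PlantParameters,
    loop: LoopParameters,
    grid: TimeGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise component of eye position for a batch of trials.

    ``C2_bar``/``C3_bar`` are (n_trials, T) mean commands.  Returns the
    (n_trials, T) eye-position noise to be added to the mean trajectories.
    """
    n_tr, T = C2_bar.shape
    h = grid.step
    sqh = np.sqrt(h)
    c2n = np.zeros((n_tr, T))
    c2pre = np.zeros((n_tr, T))
    if nc.k_PBN > 0:
        d = grid.delay_samples(loop.delay)
        if d == 0 and loop.g > 0:
            # the zero-delay loop is implicit per sample; supported only in
            # the impulse-response path, not in stochastic simulation
            raise ValueError("stochastic loop simulation requires delay >= one step")
        csum = np.zeros((n_tr, T))  # csum[:, j] = sum of c2n[:, :j+1]
        run = np.zeros(n_tr)
        for k in range(T):
            pre = -loop.g * h * csum[:, k - d] if k - d >= 0 else np.zeros(n_tr)
            sd = nc.k_PBN * np.abs(C2_bar[:, k] + pre) / sqh
            r = sd * rng.standard_normal(n_tr)
            c2pre[:, k] = pre
            c2n[:, k] = pre + r
            run = run + c2n[:, k]
            csum[:, k] = run
    # pulse-step of the C2 noise (left-Riemann integral excluding current)
    integ = np.concatenate([np.zeros((n_tr, 1)), np.cumsum(c2n[:, :-1], axis=1)], axis=1) * h
    c3n = plant.tau1 * c2n + integ
    c3tot = c3n
    if nc.k_ON > 0:
        # scaling excludes the current sample's direct PBN feedthrough
        c3n_pre = plant.tau1 * c2pre + integ
        sd_on = nc.k_ON * np.abs(C3_bar + c3n_pre) / sqh
        c3tot = c3n + sd_on * rng.standard_normal((n_tr, T))
    if not np.any(c3tot):
        return np.zeros((n_tr, T))
    p_u = plant_impulse_response(plant, grid) * h
    return fftconvolve(c3tot, p_u[np.newaxis, :], axes=1)[:, :T]


def _truncnorm(rng, center, sd, lo, hi, size):
    from scipy.stats import truncnorm

    if sd <= 0:
        return np.full(size, center)
    a, b = (lo - center) / sd, (hi - center) / sd
    return truncnorm.rvs(a, b, loc=center, scale=sd, size=size, random_state=rng)


def generate_ensemble(
    n_trials: int,
    config: ConditionConfig | str,
    seed: int | None = None,
    horizon: float | None = None,
) -> TrialEnsemble:
    """Generate a reproducible ensemble of noisy trials for one condition.

    Same (config, seed) → bitwise-identical ensembles.  Planned amplitudes
    are drawn ``Normal(Ā, k_A²·Ā²)`` (clipped to the main-sequence model's
    supported range); motor errors are an independent truncated-normal
    target jitter around the motor-error class center.
    """
    if isinstance(config, str):
        config = condition_preset(config)
    if n_trials < 2:
        raise ValueError("need n_trials >= 2")
    rng = np.random.default_rng(seed)
    ms, nc, plant, loop = config.main_sequence, config.noise, config.plant, config.loop

    A = rng.normal(config.A_bar, nc.k_A * config.A_bar, size=n_trials) if nc.k_A > 0 else np.full(n_trials, config.A_bar)
    A = np.clip(A, *ms.A_range)
    me = _truncnorm(rng, config.motor_error_center, config.motor_error_sd,
                    *config.motor_error_bounds, size=n_trials)

    if horizon is None:
        horizon = float(np.max(ms.duration(A))) + config.post_margin
    grid = TimeGrid.for_duration(horizon, config.step)
    t = grid.times

    # mean paths and commands per trial (broadcast over amplitudes)
    v, vd, vdd = _velocity_derivs_matrix(ms, t, A)
    ybar = cumulative_trapezoid(v, t, axis=1, initial=0.0)
    C2b = plant.tau2 * plant.tau3 * vdd + (plant.tau2 + plant.tau3) * vd + v
    C3b = plant.tau1 * C2b + plant.tau2 * plant.tau3 * vd + (plant.tau2 + plant.tau3) * v + ybar

    ynoise = _simulate_noise_matrix(C2b, C3b, nc, plant, loop, grid, rng)
    Y = ybar + ynoise

    # resample to the output data rate
    ds = max(1, int(round(1.0 / (config.step * config.output_rate))))
    Yo, to = Y[:, ::ds], t[::ds]

    det = detect_matrix(Yo, rate=1.0 / (to[1] - to[0]))
    return TrialEnsemble(
        time=to,
        positions=Yo,
        motor_errors=me,
        planned_amplitudes=A,
        onsets=det["onset"],
        offsets=det["offset"],
        onset_times=det["onset_time"],
        offset_times=det["offset_time"],
        amplitudes=det["amplitude"],
        durations=det["duration"],
        peak_velocities=det["peak_velocity"],
        peak_indices=det["peak_index"],
        condition=config.name,
        config=config,
        seed=seed,
    )


def _velocity_derivs_matrix(ms: MainSequenceModel, t: np.ndarray, A: np.ndarray):
    """(v, v̇, v̈) stacked over an amplitude vector."""
    n = len(A)
    v = np.empty((n, len(t)))
    vd = np.empty_like(v)
    vdd = np.empty_like(v)
    # distinct amplitudes share profile evaluations
    uniq, inv = np.unique(A, return_inverse=True)
    for j, a in enumerate(uniq):
        vi, vdi, vddi = ms.velocity_derivatives(t, float(a))
        rows = np.flatnonzero(inv == j)
        v[rows], vd[rows], vdd[rows] = vi, vdi, vddi
    return v, vd, vdd


def simulate_trial(
    A_planned: float,
    nc: NoiseCoefficients,
    plant: PlantParameters,
    loop: LoopParameters,
    ms: MainSequenceModel,
    seed: int | None = None,
    step: float = 5e-4,
    output_rate: float = 1000.0,
    post_margin: float = 0.040,
) -> SaccadeTrace:
    """Simulate a single noisy trial at a fixed planned amplitude."""
    cfg = ConditionConfig(
        name="single", A_bar=A_planned,
        noise=NoiseCoefficients(k_A=0.0, k_ON=nc.k_ON, k_PBN=nc.k_PBN),
        loop=loop, plant=plant, main_sequence=ms,
        motor_error_sd=0.0, motor_error_center=A_planned,
        motor_error_bounds=(A_planned - 1, A_planned + 1),
        step=step, output_rate=output_rate, post_margin=post_margin,
    )
    ens = generate_ensemble(2, cfg, seed=seed)
    return next(ens.traces())


def generate_session(
    n_per_target: int,
    config: ConditionConfig | str,
    targets: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    seed: int | None = None,
) -> TrialEnsemble:
    """Simulate a whole recording session: blocks of trials at several
    target eccentricities, merged on a common time base.

    Each block reuses the condition's noise and dynamics parameters; the
    mean planned amplitude of a block is the target eccentricity scaled by
    the condition's gain (``A_bar / motor_error_center``).  Sessions feed
    the amplitude-binned family estimation and main-sequence fits.
    """
    if isinstance(config, str):
        config = condition_preset(config)
    gain = config.A_bar / config.motor_error_center
    ms = config.main_sequence
    amps = [min(gain * tgt, ms.A_range[1] - 1e-9) for tgt in targets]
    horizon = float(max(ms.duration(np.asarray(amps)))) + config.post_margin
    ss = np.random.SeedSequence(seed)
    parts = []
    for tgt, A_tgt, child in zip(targets, amps, ss.spawn(len(targets))):
        cfg = replace(
            config,
            A_bar=A_tgt,
            motor_error_center=tgt,
            motor_error_bounds=(tgt - 2.5, tgt + 2.5),
        )
        block_seed = int(child.generate_state(1)[0] % (2**31))
        parts.append(generate_ensemble(n_per_target, cfg, seed=block_seed, horizon=horizon))
    first = parts[0]
    return TrialEnsemble(
        time=first.time,
        positions=np.vstack([p.positions for p in parts]),
        motor_errors=np.concatenate([p.motor_errors for p in parts]),
        planned_amplitudes=np.concatenate([p.planned_amplitudes for p in parts]),
        onsets=np.concatenate([p.onsets for p in parts]),
        offsets=np.concatenate([p.offsets for p in parts]),
        onset_times=np.concatenate([p.onset_times for p in parts]),
        offset_times=np.concatenate([p.offset_times for p in parts]),
        amplitudes=np.concatenate([p.amplitudes for p in parts]),
        durations=np.concatenate([p.durations for p in parts]),
        peak_velocities=np.concatenate([p.peak_velocities for p in parts]),
        peak_indices=np.concatenate([p.peak_indices for p in parts]),
        condition=config.name,
        config=config,
        seed=seed,
    )
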