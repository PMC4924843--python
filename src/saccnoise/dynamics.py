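"""Discretized linear saccade-generator dynamics.

The saccadic burst generator is modeled as a linear chain: a premotor burst
neuron (PBN) enclosed in an internal feedback loop (delayed integrator, gain
``g``, delay ``Δt``), the classical pulse-step superposition converting the
velocity command ``C2`` into the oculomotor-neuron command ``C3``, and a
third-order low-pass plant (time constants ``τ1 > τ2 > τ3``) converting ``C3``
into eye position.  This module provides the impulse responses of each stage,
forward simulation through the plant, and the inversion that recovers the
internal commands from an observed mean trajectory.

Discrete-time conventions
-------------------------
All responses live on a uniform grid (default step 0.5 ms) and are stored as
*unit-sample responses*: the response of the discrete-time simulation to an
input of value 1 at a single sample.  For a strictly proper continuous system
with impulse response ``f(t)`` the unit-sample response is ``f(t_k)·step``; a
direct feedthrough (a Dirac delta in continuous time) appears as a plain
coefficient at lag 0 (``m[0] = 1`` for the feedback loop).  Integrals are
left-Riemann sums excluding the current sample, matching the loop recursion
used by the Monte-Carlo generator, so analytic propagation and simulation
share one discretization exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PlantParameters",
    "LoopParameters",
    "TimeGrid",
    "ImpulseResponseSet",
    "ControlSignals",
    "plant_impulse_response",
    "closed_loop_impulse_response",
    "pulse_step_filter",
    "forward_simulate_plant",
    "invert_to_C2",
    "invert_to_C3",
    "impulse_responses",
    "gaussian_lowpass",
    "GAUSSIAN_LOWPASS_HZ",
]

#: Cutoff (3 dB) of the zero-phase Gaussian low-pass applied to raw traces.
GAUSSIAN_LOWPASS_HZ = 100.0

#: Number of samples at each edge of a numerically differentiated series that
#: rely on one-sided stencils and should be treated as invalid.
N_EDGE_INVALID = 3


@dataclass(frozen=True)
class PlantParameters:
    """Time constants of the third-order oculomotor plant (seconds)."""

    tau1: float = 0.223
    tau2: float = 0.014
    tau3: float = 0.004

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau2 > self.tau3 > 0):
            raise ValueError(
                "plant time constants must satisfy tau1 > tau2 > tau3 > 0; "
                f"got {self.tau1}, {self.tau2}, {self.tau3}"
            )

    @property
    def taus(self) -> tuple[float, float, float]:
        return (self.tau1, self.tau2, self.tau3)


@dataclass(frozen=True)
class LoopParameters:
    """Internal feedback loop: integrator gain ``g`` (1/s) and delay (s)."""

    g: float = 240.0
    delay: float = 0.004

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("feedback gain g must be >= 0")
        if self.delay < 0:
            raise ValueError("feedback delay must be >= 0")

    @property
    def stable(self) -> bool:
        """Stability of the delayed-integrator loop (g·delay < π/2)."""
        return self.g * self.delay < np.pi / 2


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: interval ``step`` (s) and sample count."""

    step: float = 5e-4
    n_samples: int = 200

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.step

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) * self.step

    def delay_samples(self, delay: float) -> int:
        """Delay as an integer sample count; warns if rounding is coarse."""
        d = int(round(delay / self.step))
        if delay > 0 and abs(d * self.step - delay) > 0.1 * delay:
            warnings.warn(
                f"feedback delay {delay} s rounded to {d} samples "
                f"({d * self.step} s); rounding error exceeds 10%",
                stacklevel=2,
            )
        return d

    @classmethod
    def for_duration(cls, duration: float, step: float = 5e-4) -> "TimeGrid":
        return cls(step=step, n_samples=int(round(duration / step)) + 1)


@dataclass(frozen=True)
class ControlSignals:
    """Mean internal commands: C2 (premotor burst, deg/s) and C3 (deg)."""

    C2_bar: np.ndarray
    C3_bar: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.C2_bar)) and np.all(np.isfinite(self.C3_bar))):
            raise ValueError("control signals must be finite")


def plant_impulse_response(plant: PlantParameters, grid: TimeGrid) -> np.ndarray:
    """Impulse response ``p(t)`` of 1/((τ1 s+1)(τ2 s+1)(τ3 s+1)), units 1/s.

    Computed from the exact partial-fraction expansion
    ``p(t) = Σ_i exp(-t/τ_i)·τ_i / Π_{j≠i}(τ_i − τ_j)``.  The relative degree
    is 3, so ``p(0) = 0``, and the DC gain is 1 so the running integral of
    ``p`` converges to 1.
    """
    taus = np.asarray(plant.taus)
    if len(np.unique(taus)) < 3:
        raise ValueError("repeated plant time constants are not supported")
    if grid.step > plant.tau3 / 4:
        warnings.warn(
            f"grid step {grid.step} s is coarse relative to tau3={plant.tau3} s; "
            "impulse-response discretization may be inaccurate",
            stacklevel=2,
        )
    t = grid.times
    p = np.zeros_like(t)
    for i in range(3):
        denom = np.prod([taus[i] - taus[j] for j in range(3) if j != i])
        p += np.exp(-t / taus[i]) * taus[i] / denom
    p[0] = 0.0  # exact: the three residues cancel at t=0
    return p


def closed_loop_impulse_response(loop: LoopParameters, grid: TimeGrid) -> np.ndarray:
    """Unit-sample response ``m`` of the loop transfer 1/(1 + (g/s)·e^(−sΔt)).

    ``m[0] = 1`` is the direct feedthrough; subsequent samples follow the
    delayed-integrator recursion ``m[k] = −g·step·Σ_{j ≤ k−d} m[j]`` with
    ``d = delay/step``.  Unstable configurations (g·delay ≥ π/2) produce a
    warning, not an exception, because parameter fits may probe them.
    """
    if not loop.stable:
        warnings.warn(
            f"delayed-integrator loop with g={loop.g}/s, delay={loop.delay}s "
            "is unstable (g*delay >= pi/2); response will oscillate/diverge",
            stacklevel=2,
        )
    h = grid.step
    n = grid.n_samples
    d = grid.delay_samples(loop.delay)
    m = np.empty(n)
    m[0] = 1.0
    # csum_hist[j] = sum of m[0..j]
    csum_hist = np.empty(n)
    csum_hist[0] = 1.0
    for k in range(1, n):
        if d == 0:
            # zero-delay loop: the recursion is implicit in m[k]
            m[k] = -loop.g * h * csum_hist[k - 1] / (1.0 + loop.g * h)
        elif k - d >= 0:
            m[k] = -loop.g * h * csum_hist[k - d]
        else:
            m[k] = 0.0
        csum_hist[k] = csum_hist[k - 1] + m[k]
    return m


def pulse_step_filter(u: np.ndarray, plant: PlantParameters, grid: TimeGrid) -> np.ndarray:
    """Pulse-step superposition ``τ1·u(t) + ∫u`` (rectangle rule).

    The cumulative integral is the left-Riemann sum excluding the current
    sample, the same rule used in the time-domain loop simulation.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("pulse_step_filter input must be finite")
    integral = np.concatenate(([0.0], np.cumsum(u[:-1]))) * grid.step
    return plant.tau1 * u + integral


def forward_simulate_plant(C2: np.ndarray, plant: PlantParameters, grid: TimeGrid) -> np.ndarray:
    """Eye position from the burst command via Y/C2 = 1/(s(τ2 s+1)(τ3 s+1)).

    Uses a first-order-hold discretization of the continuous system (exact
    for piecewise-linear input), appropriate for the smooth burst commands
    this transfer is driven with.  ``y[0] = 0``.
    """
    C2 = np.asarray(C2, dtype=float)
    t2, t3 = plant.tau2, plant.tau3
    num = [1.0]
    den = [t2 * t3, t2 + t3, 1.0, 0.0]
    dsys = signal.cont2discrete((num, den), grid.step, method="foh")
    b, a = np.squeeze(dsys[0]), dsys[1]
    y = signal.lfilter(np.atleast_1d(b), np.atleast_1d(a), C2)
    return y


def invert_to_C2(
    y_bar: np.ndarray,
    plant: PlantParameters,
    grid: TimeGrid,
    presmooth_hz: float | None = None,
) -> np.ndarray:
    """Recover the burst command: ``C2 = τ2 τ3 y⃛ + (τ2+τ3) ÿ + ẏ``.

    Derivatives are cascaded centered differences (``np.gradient`` applied
    three times).  The outermost ``N_EDGE_INVALID`` samples at each end use
    one-sided stencils and should be treated as invalid.  ``presmooth_hz``
    optionally applies the zero-phase Gaussian low-pass first (use
    ``GAUSSIAN_LOWPASS_HZ`` for raw recorded traces; leave ``None`` for
    already-smooth model trajectories).
    """
    y = np.asarray(y_bar, dtype=float)
    if y.size < 7:
        raise ValueError("series too short for third-order differentiation")
    if presmooth_hz is not None:
        y = gaussian_lowpass(y, grid.step, presmooth_hz)
    h = grid.step
    v = np.gradient(y, h)
    a = np.gradient(v, h)
    j = np.gradient(a, h)
    return plant.tau2 * plant.tau3 * j + (plant.tau2 + plant.tau3) * a + v


def invert_to_C3(C2: np.ndarray, plant: PlantParameters, grid: TimeGrid) -> np.ndarray:
    """Oculomotor command ``C3 = τ1·C2 + ∫C2`` (pulse + step)."""
    return pulse_step_filter(C2, plant, grid)


def gaussian_lowpass(x: np.ndarray, step: float, cutoff_hz: float = GAUSSIAN_LOWPASS_HZ, axis: int = -1) -> np.ndarray:
    """Symmetric (zero-phase) Gaussian low-pass with 3 dB point at ``cutoff_hz``.

    The Gaussian kernel with SD σ has |H(f)| = exp(−2π²σ²f²); solving
    |H(f_c)|² = 1/2 gives σ = sqrt(ln 2 / 2) / (2π f_c).
    """
    from scipy.ndimage import gaussian_filter1d

    sigma_s = np.sqrt(np.log(2.0) / 2.0) / (2.0 * np.pi * cutoff_hz)
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_s / step, axis=axis, mode="nearest")


@dataclass(frozen=True)
class ImpulseResponseSet:
    """Unit-sample responses of every noise path, on a common grid.

    Attributes
    ----------
    p : continuous plant impulse response sampled on the grid (1/s).
    p_u : plant unit-sample response ``p·step`` (noise at C3 → eye position).
    m : loop unit-sample response (noise at C2 → C2), ``m[0] = 1``.
    n : pulse-step of ``m`` (noise at C2 → C3); direct feedthrough ``τ1`` at
        lag 0.
    q : discrete convolution ``n ⊛ p_u`` (noise at C2 → eye position).
    """

    p: np.ndarray
    p_u: np.ndarray
    m: np.ndarray
    n: np.ndarray
    q: np.ndarray
    grid: TimeGrid
    plant: PlantParameters = field(default_factory=PlantParameters)
    loop: LoopParameters = field(default_factory=LoopParameters)


def impulse_responses(plant: PlantParameters, loop: LoopParameters, grid: TimeGrid) -> ImpulseResponseSet:
    """Assemble the impulse-response set for one (plant, loop, grid) triple."""
    p = plant_impulse_response(plant, grid)
    p_u = p * grid.step
    m = closed_loop_impulse_response(loop, grid)
    n = pulse_step_filter(m, plant, grid)
    q = np.convolve(n, p_u)[: grid.n_samples]
    return ImpulseResponseSet(p=p, p_u=p_u, m=m, n=n, q=q, grid=grid, plant=plant, loop=loop)
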