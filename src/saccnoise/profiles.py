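"""Parametric main-sequence family of mean saccade trajectories.

A saccade's mean (noise-free) trajectory is determined by its planned
amplitude ``A`` through the main sequence: duration grows linearly with
amplitude (slope ``alpha``), peak velocity follows a saturating power law,
and the deceleration phase occupies a fixed fraction of the movement.  The
velocity profile is a two-piece power-of-smoothstep bump,

    v(t) = Vp(A) · S7(u)^λ ,

with ``S7(u) = 35u⁴ − 84u⁵ + 70u⁶ − 20u⁷`` (the C³ smoothstep), ``u`` the
normalized time within the rise piece ``[0, s_p·D]`` or the mirrored fall
piece, and ``s_p = 1 − decel_fraction`` the peak-velocity fraction.  The
exponent ``λ(A) > 1/2`` is solved so the profile integrates exactly to ``A``;
``λ > 1/2`` keeps the velocity twice continuously differentiable (position is
C³), which the third-order inversion of the plant requires.

The family is deliberately kinematic: it emulates the empirical regularities
of 10-deg-motor-error macaque saccades (duration ≈ 40 ms, peak velocity
≈ 430 deg/s, deceleration fraction ≈ 55% at 10 deg) without committing to a
specific neural optimality principle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MainSequenceModel"]


def _s7(u: np.ndarray) -> np.ndarray:
    return u**4 * (35.0 - 84.0 * u + 70.0 * u**2 - 20.0 * u**3)


def _s7_d1(u: np.ndarray) -> np.ndarray:
    return 140.0 * u**3 - 420.0 * u**4 + 420.0 * u**5 - 140.0 * u**6


def _s7_d2(u: np.ndarray) -> np.ndarray:
    return 420.0 * u**2 - 1680.0 * u**3 + 2100.0 * u**4 - 840.0 * u**5


# cached λ ↦ ∫ S7^λ du lookup used to solve the amplitude constraint
_LAM_GRID = np.linspace(0.501, 8.0, 400)
_U_QUAD = (np.arange(2000) + 0.5) / 2000.0
_I_GRID = np.array([np.mean(_s7(_U_QUAD) ** lam) for lam in _LAM_GRID])


def _solve_lambda(target_integral: float) -> float:
    """Exponent λ with ∫₀¹ S7(u)^λ du = target (monotone decreasing in λ)."""
    if not (_I_GRID[-1] < target_integral < _I_GRID[0]):
        raise ValueError(
            f"velocity-profile form factor {target_integral:.3f} outside the "
            f"supported range ({_I_GRID[-1]:.3f}, {_I_GRID[0]:.3f}); "
            "amplitude outside the main-sequence model's smooth regime"
        )
    # _I_GRID decreases with λ → interpolate on reversed arrays
    return float(np.interp(target_integral, _I_GRID[::-1], _LAM_GRID[::-1]))


@dataclass(frozen=True)
class MainSequenceModel:
    """Amplitude-parameterized, self-similar family of mean trajectories.

    The family is exactly shape-invariant: ``ȳ(t, A) = A·F(t/D(A))`` with a
    single velocity shape shared by all amplitudes.  Consequences that the
    analysis relies on: the amplitude linearization behind the planning-noise
    formulas is exact on the duration-normalized axis, and the implied peak
    velocity ``Vp(A) = A/(D(A)·∫shape)`` follows a realistic saturating main
    sequence (the shape integral is fixed by requiring ``Vp(A_ref) =
    vpeak_ref``).

    Parameters
    ----------
    A_ref, D_ref : reference amplitude (deg) and duration at it (s).
    alpha : main-sequence slope of amplitude on duration (deg/ms).
    decel_fraction : deceleration duration / total duration.
    vpeak_ref : peak velocity at ``A_ref`` (deg/s).
    A_range : supported amplitude range (deg).
    """

    A_ref: float = 10.0
    D_ref: float = 0.040
    alpha: float = 0.66
    decel_fraction: float = 0.55
    vpeak_ref: float = 430.0
    A_range: tuple[float, float] = (2.0, 25.0)

    def __post_init__(self) -> None:
        if not (0 < self.decel_fraction < 1):
            raise ValueError("decel_fraction must be in (0, 1)")
        if self.duration(self.A_range[0]) <= 0:
            raise ValueError("duration must stay positive over A_range")
        # solve the shape exponent once; raises if the reference point is
        # outside the smooth (λ > 1/2) regime
        _solve_lambda(self.A_ref / (self.vpeak_ref * self.D_ref))

    # -- scalar main-sequence relations ------------------------------------
    def duration(self, A) -> np.ndarray | float:
        """Total movement duration D(A) = D_ref + (A − A_ref)/alpha, in s."""
        return self.D_ref + (np.asarray(A, dtype=float) - self.A_ref) / (self.alpha * 1000.0)

    @property
    def _lambda(self) -> float:
        return _solve_lambda(self.A_ref / (self.vpeak_ref * self.D_ref))

    @property
    def _shape_integral(self) -> float:
        return self.A_ref / (self.vpeak_ref * self.D_ref)

    def peak_velocity(self, A) -> np.ndarray | float:
        """Peak velocity implied by self-similarity: A/(D(A)·∫shape)."""
        A = np.asarray(A, dtype=float)
        return A / (self.duration(A) * self._shape_integral)

    @property
    def peak_fraction(self) -> float:
        """Fraction of the duration at which velocity peaks."""
        return 1.0 - self.decel_fraction

    def _check_range(self, A: np.ndarray) -> None:
        lo, hi = self.A_range
        if np.any(A < lo) or np.any(A > hi):
            raise ValueError(f"amplitude outside supported range [{lo}, {hi}] deg")

    def shape_exponent(self, A) -> np.ndarray:
        """Shared shape exponent λ (amplitude-independent by design)."""
        A = np.atleast_1d(np.asarray(A, dtype=float))
        self._check_range(A)
        return np.full(A.shape, self._lambda)

    # -- profile evaluation -------------------------------------------------
    def _pieces(self, t: np.ndarray, A: np.ndarray):
        """Broadcast helpers: (u, du/dt, valid) for rise/fall pieces."""
        D = np.asarray(self.duration(A))
        sp = self.peak_fraction
        t_pk = sp * D
        rise = t <= t_pk
        u = np.where(rise, t / np.maximum(t_pk, 1e-12), (D - t) / np.maximum((1 - sp) * D, 1e-12))
        u = np.clip(u, 0.0, 1.0)
        dudt = np.where(rise, 1.0 / np.maximum(t_pk, 1e-12), -1.0 / np.maximum((1 - sp) * D, 1e-12))
        inside = (t >= 0) & (t <= D)
        return u, dudt, inside

    def velocity(self, t: np.ndarray, A) -> np.ndarray:
        """Velocity profile (deg/s); zero outside [0, D(A)].  Broadcasts
        ``t`` (time axis) against ``A`` (per-trial amplitudes)."""
        t = np.asarray(t, dtype=float)
        A = np.asarray(A, dtype=float)
        lam = self.shape_exponent(A).reshape(np.atleast_1d(A).shape)
        if A.ndim:
            t = t[np.newaxis, :]
            A = A[:, np.newaxis]
            lam = lam[:, np.newaxis]
        else:
            lam = float(lam[0])
        u, _, inside = self._pieces(t, A)
        vp = self.peak_velocity(A)
        s = _s7(u)
        v = vp * np.where(s > 0, s, 0.0) ** lam
        return np.where(inside, v, 0.0)

    def velocity_derivatives(self, t: np.ndarray, A: float):
        """(v, v̇, v̈) for a scalar amplitude; used for exact inversion."""
        t = np.asarray(t, dtype=float)
        lam = float(self.shape_exponent(A)[0])
        u, dudt, inside = self._pieces(t, float(A))
        vp = float(self.peak_velocity(A))
        s = _s7(u)
        s1 = _s7_d1(u)
        s2 = _s7_d2(u)
        pos = s > 0
        sl = np.where(pos, s, 1.0)
        v = vp * np.where(pos, sl**lam, 0.0)
        dv_du = vp * lam * np.where(pos, sl ** (lam - 1.0) * s1, 0.0)
        # λ > 1/2 keeps s^(λ-2)·s1² = O(u^{4λ-2}) finite at the endpoints
        d2v_du2 = vp * lam * np.where(
            pos, (lam - 1.0) * sl ** (lam - 2.0) * s1**2 + sl ** (lam - 1.0) * s2, 0.0
        )
        vdot = dv_du * dudt
        vddot = d2v_du2 * dudt**2
        z = ~inside
        for arr in (v, vdot, vddot):
            arr[z] = 0.0
        return v, vdot, vddot

    def position(self, t: np.ndarray, A) -> np.ndarray:
        """Mean eye-position trajectory ȳ(t, A) (deg), cumulative trapezoid
        of the velocity profile; holds at A after the movement ends."""
        from scipy.integrate import cumulative_trapezoid

        v = self.velocity(t, A)
        t = np.asarray(t, dtype=float)
        return cumulative_trapezoid(v, t, axis=-1, initial=0.0)
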