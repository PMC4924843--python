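"""Analytic variance/covariance trajectory predictions per noise source.

For each of the three noise sources the variance trajectory ``var_y(t)`` and
the covariance-with-end-position trajectory ``cov_ye(t)`` are computed in
closed form given a mean-trajectory family and the dynamics parameters:

* planning noise — ``var = (∂ȳ/∂Ā)²·σ_A²``, ``cov = (∂ȳ/∂Ā)·σ_A²`` with
  ``σ_A² = k_A²·Ā²`` and the amplitude derivative estimated by the
  difference quotient of family members at ``Ā ± Δ/2``;
* ON noise — white noise of power density ``Q_ON = k_ON²·(C̄3² + var_C3)``
  filtered by the plant: ``var(t) = ∫Q_ON(τ)·p²(t−τ)dτ`` and
  ``cov(t) = ∫Q_ON(τ)·p(t−τ)·p(D−τ)dτ``;
* PBN noise — white noise of power density ``Q_PBN`` injected inside the
  feedback loop and filtered by ``q = n ⊛ p``.  Because the loop feeds the
  noise back onto its own scaling signal, ``Q_PBN`` solves a linear Volterra
  integral equation of the second kind,
  ``Q(t) = k²·C̄2²(t) + k²·∫Q(τ)·m²(t−τ)dτ``, evaluated by forward
  recursion.

All integrals are discretized on the simulation grid with the same
left-Riemann/unit-sample conventions the Monte-Carlo generator uses, then
resampled to the 100-sample normalized axis.  The three sources are
independent, so the total prediction is their sample-wise sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    ImpulseResponseSet,
    LoopParameters,
    PlantParameters,
    TimeGrid,
    impulse_responses,
    invert_to_C2,
    invert_to_C3,
)
from .profiles import MainSequenceModel

__all__ = [
    "MeanFamily",
    "NoiseComponentPrediction",
    "TotalPrediction",
    "PredictionEngine",
    "planning_derivative",
    "planning_var_cov",
    "on_noise_var_cov",
    "pbn_power_density",
    "pbn_var_cov",
    "total_prediction",
]


@dataclass(frozen=True)
class MeanFamily:
    """Mean-trajectory family around Ā needed by the analytic predictions.

    ``y_norm_plus/minus`` are the family members at ``Ā ± Δ/2``, each
    normalized on its own movement duration and resampled to ``n_norm``
    points (their last samples are therefore the member amplitudes exactly).
    ``C2_bar``/``C3_bar`` are the center member's internal commands on the
    raw grid covering [0, D̄].
    """

    grid: TimeGrid
    C2_bar: np.ndarray
    C3_bar: np.ndarray
    y_raw: np.ndarray
    y_norm_plus: np.ndarray
    y_norm_minus: np.ndarray
    A_bar: float
    D_bar: float
    delta: float = 5.0
    n_norm: int = 100

    @classmethod
    def from_model(
        cls,
        ms: MainSequenceModel,
        A_bar: float,
        plant: PlantParameters | None = None,
        delta: float = 5.0,
        step: float = 5e-4,
        n_norm: int = 100,
    ) -> "MeanFamily":
        """Build the family from the parametric main-sequence model (exact
        internal commands from the profile's closed-form derivatives)."""
        from .synth import mean_controls

        plant = plant or PlantParameters()
        D = float(ms.duration(A_bar))
        grid = TimeGrid.for_duration(D, step)
        C2, C3, y = mean_controls(A_bar, ms, plant, grid)
        from scipy.interpolate import CubicSpline

        members = {}
        for a in (A_bar + delta / 2.0, A_bar - delta / 2.0):
            Da = float(ms.duration(a))
            ga = TimeGrid.for_duration(Da, step)
            ya = ms.position(ga.times, a)
            s = np.linspace(0.0, 1.0, n_norm)
            ym = CubicSpline(ga.times, ya)(s * Da)
            ym[-1] = a  # ȳ(D, A) = A by definition of the family
            members[a] = ym
        return cls(
            grid=grid, C2_bar=C2, C3_bar=C3, y_raw=y,
            y_norm_plus=members[A_bar + delta / 2.0],
            y_norm_minus=members[A_bar - delta / 2.0],
            A_bar=float(A_bar), D_bar=D, delta=delta, n_norm=n_norm,
        )

    @classmethod
    def from_trajectories(
        cls,
        t: np.ndarray,
        y_bar: np.ndarray,
        y_plus: np.ndarray,
        y_minus: np.ndarray,
        A_bar: float,
        D_bar: float,
        plant: PlantParameters | None = None,
        delta: float = 5.0,
        step: float = 5e-4,
        n_norm: int = 100,
        presmooth_hz: float | None = 100.0,
    ) -> "MeanFamily":
        """Build the family from measured mean trajectories.

        ``y_bar`` is the center mean trajectory sampled at times ``t``
        (onset at 0); internal commands are recovered by numerical
        inversion after zero-phase Gaussian smoothing.  ``y_plus/minus``
        must already be on the ``n_norm``-sample normalized axis.
        """
        plant = plant or PlantParameters()
        grid = TimeGrid.for_duration(D_bar, step)
        # pad with rest / hold to keep the differentiation stencils clean
        npad = 8
        yg = np.interp(grid.times, t, y_bar)
        ypad = np.concatenate([np.zeros(npad), yg, np.full(npad, yg[-1])])
        gpad = TimeGrid(step=step, n_samples=len(ypad))
        C2p = invert_to_C2(ypad, plant, gpad, presmooth_hz=presmooth_hz)
        C2 = C2p[npad:-npad]
        C3 = invert_to_C3(C2, plant, grid)
        return cls(
            grid=grid, C2_bar=C2, C3_bar=C3, y_raw=yg,
            y_norm_plus=np.asarray(y_plus, float),
            y_norm_minus=np.asarray(y_minus, float),
            A_bar=float(A_bar), D_bar=float(D_bar), delta=delta, n_norm=n_norm,
        )


@dataclass(frozen=True)
class NoiseComponentPrediction:
    """One source's predicted trajectories on the normalized axis."""

    source: str
    var: np.ndarray
    cov: np.ndarray
    Q: np.ndarray | None = None   # power density on the raw grid


@dataclass(frozen=True)
class TotalPrediction:
    """Superposed prediction plus the per-source breakdown."""

    t_norm: np.ndarray
    var: np.ndarray
    cov: np.ndarray
    components: dict = field(default_factory=dict)

    @property
    def rho(self) -> np.ndarray:
        denom = np.sqrt(self.var * self.var[-1])
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.cov / np.where(denom > 0, denom, 1.0), np.nan)


# -- planning noise ---------------------------------------------------------

def planning_derivative(y_plus: np.ndarray, y_minus: np.ndarray, delta: float) -> np.ndarray:
    """Amplitude sensitivity ∂ȳ/∂Ā(t) as the empirical difference quotient
    of family members at Ā ± Δ/2 on the common normalized axis."""
    y_plus = np.asarray(y_plus, float)
    y_minus = np.asarray(y_minus, float)
    if y_plus.shape != y_minus.shape:
        raise ValueError("family members must share the normalized axis")
    return (y_plus - y_minus) / delta


def planning_var_cov(derivative: np.ndarray, k_A: float, A_bar: float):
    """Planning-noise trajectories: var = (∂ȳ/∂Ā)²σ_A², cov = (∂ȳ/∂Ā)σ_A²
    with σ_A² = k_A²·Ā².  The implied correlation is 1 wherever the
    derivative is positive."""
    if k_A < 0:
        raise ValueError("k_A must be >= 0")
    sigma2 = k_A**2 * A_bar**2
    d = np.asarray(derivative, float)
    return d**2 * sigma2, d * sigma2


# -- convolution helpers ----------------------------------------------------

def _var_conv(Q: np.ndarray, f_u: np.ndarray, h: float) -> np.ndarray:
    """var(t_k) = Σ_i Q_i f_u²[k−i] / h  (discrete ∫Q(τ)f²(t−τ)dτ)."""
    n = len(Q)
    return np.convolve(Q, f_u[:n] ** 2)[:n] / h


def _cov_conv(Q: np.ndarray, f_u: np.ndarray, h: float) -> np.ndarray:
    """cov(t_k) = Σ_i Q_i f_u[k−i] f_u[K−i] / h with K the end index."""
    n = len(Q)
    w = f_u[n - 1 :: -1][:n]
    return np.convolve(Q * w, f_u[:n])[:n] / h


# -- ON noise ---------------------------------------------------------------

def on_noise_var_cov(
    C3_bar: np.ndarray,
    var_C3: np.ndarray | None,
    k_ON: float,
    responses: ImpulseResponseSet,
    D: float,
):
    """ON-noise trajectories on the raw grid.

    ``Q_ON = k_ON²·(C̄3² + var_C3)``; with no upstream noise (var_C3 = 0)
    this reduces to the classical signal-dependent motor-noise power
    density ``k_ON²·C̄3²``.  Returns (var, cov, Q_ON).
    """
    h = responses.grid.step
    C3_bar = np.asarray(C3_bar, float)
    vC3 = np.zeros_like(C3_bar) if var_C3 is None else np.asarray(var_C3, float)
    Q = k_ON**2 * (C3_bar**2 + vC3)
    return _var_conv(Q, responses.p_u, h), _cov_conv(Q, responses.p_u, h), Q


# -- PBN noise --------------------------------------------------------------

def pbn_power_density(C2_bar: np.ndarray, k_PBN: float, m: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Power density of the loop-injected noise by Volterra recursion.

    Solves ``Q(t) = k²·C̄2²(t) + k²·∫₀ᵗ Q(τ)·m²(t−τ)dτ`` forward in time,
    starting from ``Q(0) = k²·C̄2²(0)``.  The loop's direct feedthrough
    (``m[0] = 1``) appears with weight ``step`` in the denominator
    ``1 − k²·m²(0)·step``, which keeps the recursion well-posed for any
    ``k² < 1/step``.
    """
    h = grid.step
    denom = 1.0 - k_PBN**2 * m[0] ** 2 * h
    if denom <= 0:
        raise ValueError(
            "Volterra recursion ill-posed: k_PBN^2·m(0)^2·step >= 1 under the "
            "unit direct-feedthrough convention (m[0] = 1)"
        )
    C2_bar = np.asarray(C2_bar, float)
    n = len(C2_bar)
    k2 = k_PBN**2
    # continuous-time m values for lags >= 1 sample are m_u[i]/h
    msq = np.zeros(n)
    msq[1:] = (m[1 : n] / h) ** 2
    Q = np.empty(n)
    Q[0] = k2 * C2_bar[0] ** 2
    drive = k2 * C2_bar**2
    for j in range(1, n):
        fb = k2 * h * float(np.dot(Q[:j], msq[j:0:-1]))
        Q[j] = (drive[j] + fb) / denom
    return Q


def pbn_var_cov(Q_PBN: np.ndarray, responses: ImpulseResponseSet, D: float):
    """PBN-noise trajectories on the raw grid, plus the command variances.

    Returns (var, cov, var_C2, var_C3): the eye-position trajectories via
    ``q``, the burst-command variance via ``m`` and the oculomotor-command
    variance via ``n`` (the latter feeds the ON power density).  The direct
    feedthroughs of ``m`` and ``n`` enter the command variances with weight
    ``step``, matching the Volterra-recursion convention.
    """
    if np.any(Q_PBN < 0):
        raise ValueError("power density must be >= 0")
    h = responses.grid.step
    n_len = len(Q_PBN)
    var = _var_conv(Q_PBN, responses.q, h)
    cov = _cov_conv(Q_PBN, responses.q, h)
    m_tail = responses.m[:n_len].copy()
    m0, m_tail[0] = m_tail[0], 0.0
    n_tail = responses.n[:n_len].copy()
    n0, n_tail[0] = n_tail[0], 0.0
    var_C2 = _var_conv(Q_PBN, m_tail, h) + Q_PBN * m0**2 * h
    var_C3 = _var_conv(Q_PBN, n_tail, h) + Q_PBN * n0**2 * h
    return var, cov, var_C2, var_C3


# -- orchestration ----------------------------------------------------------

class PredictionEngine:
    """Caches the family-dependent quantities and predicts trajectories for
    arbitrary noise parameters (the fitting loop's inner kernel)."""

    def __init__(
        self,
        family: MeanFamily,
        plant: PlantParameters | None = None,
        delay: float = 0.004,
    ) -> None:
        self.family = family
        self.plant = plant or PlantParameters()
        self.delay = delay
        self.grid = family.grid
        self._deriv = planning_derivative(family.y_norm_plus, family.y_norm_minus, family.delta)
        self._irs_cache: dict[float, ImpulseResponseSet] = {}
        self.t_norm = np.linspace(0.0, 1.0, family.n_norm)
        self._t_frac = self.grid.times / self.grid.duration

    def _responses(self, g: float) -> ImpulseResponseSet:
        key = round(float(g), 9)
        if key not in self._irs_cache:
            if len(self._irs_cache) > 256:
                self._irs_cache.clear()
            self._irs_cache[key] = impulse_responses(
                self.plant, LoopParameters(g=float(g), delay=self.delay), self.grid
            )
        return self._irs_cache[key]

    def _resample(self, series: np.ndarray) -> np.ndarray:
        return np.interp(self.t_norm, self._t_frac, series)

    def predict(self, k_A: float, k_ON: float, k_PBN: float, g: float) -> TotalPrediction:
        fam = self.family
        D = fam.D_bar
        irs = self._responses(g)
        # PBN: Volterra power density, then q-filtered trajectories
        if k_PBN > 0:
            Q_PBN = pbn_power_density(fam.C2_bar, k_PBN, irs.m, self.grid)
            v_pbn_r, c_pbn_r, _, var_C3 = pbn_var_cov(Q_PBN, irs, D)
        else:
            Q_PBN = np.zeros(self.grid.n_samples)
            v_pbn_r = c_pbn_r = var_C3 = np.zeros(self.grid.n_samples)
        # ON: power density modulated by the upstream command variance
        v_on_r, c_on_r, Q_ON = on_noise_var_cov(fam.C3_bar, var_C3, k_ON, irs, D)
        # planning: closed form on the normalized axis
        v_pl, c_pl = planning_var_cov(self._deriv, k_A, fam.A_bar)
        comps = {
            "planning": NoiseComponentPrediction("planning", v_pl, c_pl),
            "ON": NoiseComponentPrediction("ON", self._resample(v_on_r), self._resample(c_on_r), Q_ON),
            "PBN": NoiseComponentPrediction("PBN", self._resample(v_pbn_r), self._resample(c_pbn_r), Q_PBN),
        }
        var = comps["planning"].var + comps["ON"].var + comps["PBN"].var
        cov = comps["planning"].cov + comps["ON"].cov + comps["PBN"].cov
        return TotalPrediction(t_norm=self.t_norm, var=var, cov=cov, components=comps)


def total_prediction(
    params,
    family: MeanFamily,
    plant: PlantParameters | None = None,
    delay: float = 0.004,
) -> TotalPrediction:
    """Predicted total var/cov trajectories for ``params = [k_A, k_ON,
    k_PBN, g]`` given a mean-trajectory family."""
    k_A, k_ON, k_PBN, g = (float(v) for v in params)
    return PredictionEngine(family, plant, delay).predict(k_A, k_ON, k_PBN, g)
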