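"""Noise-parameter fitting, AIC model comparison and condition contrasts.

The free parameters ``[k_A, k_ON, k_PBN, g]`` are fitted by minimizing the
mean squared error between measured and predicted variance/covariance
trajectories, MSE = ½·(⟨(Δvar)²⟩ + ⟨(Δcov)²⟩) over the 100 normalized
samples.  Reduced model variants fix individual noise sources to zero; when
PBN noise is absent the loop gain has no observable effect and is dropped
from the parameter count.  Variants are compared with
``AIC = N_obs·ln(MSE) + 2·N_par`` using the deliberately conservative
``N_obs = 6`` (three effective observations per fitted trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .dynamics import PlantParameters
from .propagation import MeanFamily, PredictionEngine
from .stats import TrajectoryStatistics

__all__ = [
    "ModelVariant",
    "FitResult",
    "VARIANTS",
    "model_variant",
    "objective_mse",
    "fit_model",
    "aic",
    "delta_aic_and_support",
    "classify_delta_aic",
    "one_sample_t",
    "contrast_conditions",
    "PARAM_BOUNDS",
]

#: Optimizer box bounds; the gain cap keeps g·Δt well below the π/2
#: delayed-integrator stability limit (≈393 1/s at Δt = 4 ms).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "k_A": (0.0, 1.0),
    "k_ON": (0.0, 1.0),
    "k_PBN": (0.0, 1.0),
    "g": (0.0, 350.0),
}

_PARAM_ORDER = ("k_A", "k_ON", "k_PBN", "g")


@dataclass(frozen=True)
class ModelVariant:
    """A full or reduced model: which parameters are free, which are fixed."""

    name: str
    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)

    @property
    def n_par(self) -> int:
        return len(self.free)

    def full_params(self, free_values) -> dict:
        p = dict(zip(self.free, (float(v) for v in free_values)))
        p.update(self.fixed)
        for name in _PARAM_ORDER:
            p.setdefault(name, 0.0)
        return p


VARIANTS: dict[str, ModelVariant] = {
    # all three sources plus the loop gain
    "full": ModelVariant("full", free=("k_A", "k_ON", "k_PBN", "g")),
    # no loop noise: g unobservable, 2 parameters
    "no_PBN": ModelVariant("no_PBN", free=("k_A", "k_ON"), fixed={"k_PBN": 0.0, "g": 0.0}),
    # the workhorse 3-parameter model (planning and ON noise merged into
    # "accumulating noise" carried by k_A)
    "no_ON": ModelVariant("no_ON", free=("k_A", "k_PBN", "g"), fixed={"k_ON": 0.0}),
}


def model_variant(name: str, k_A_fixed: float | None = None) -> ModelVariant:
    """Look up a variant; ``fixed_kA`` needs the value to pin k_A at."""
    if name == "fixed_kA":
        if k_A_fixed is None:
            raise ValueError("fixed_kA variant requires k_A_fixed")
        return ModelVariant("fixed_kA", free=("k_PBN", "g"),
                            fixed={"k_A": float(k_A_fixed), "k_ON": 0.0})
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; available: {sorted(VARIANTS)} + 'fixed_kA'")
    return VARIANTS[name]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one variant's fit to one condition's trajectories."""

    variant: str
    params: dict
    mse: float
    var_tot: float
    r2: float
    aic: float
    n_par: int
    n_obs: int
    success: bool
    n_starts: int
    seed: int | None
    at_bounds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params,
            "mse": self.mse,
            "var_tot": self.var_tot,
            "r2": self.r2,
            "aic": self.aic,
            "n_par": self.n_par,
            "n_obs": self.n_obs,
            "success": self.success,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "at_bounds": self.at_bounds,
        }


def objective_mse(
    params: dict,
    empirical: TrajectoryStatistics,
    engine: PredictionEngine,
) -> float:
    """MSE between measured and predicted var/cov trajectories (deg⁴)."""
    try:
        pred = engine.predict(params["k_A"], params["k_ON"], params["k_PBN"], params["g"])
    except (ValueError, FloatingPointError):
        return float("inf")
    r_var = empirical.var_y - pred.var
    r_cov = empirical.cov_ye - pred.cov
    mse = 0.5 * (float(np.mean(r_var**2)) + float(np.mean(r_cov**2)))
    return mse if np.isfinite(mse) else float("inf")


def _var_tot(empirical: TrajectoryStatistics) -> float:
    """Mean of the total (across-sample) variances of the two fitted
    trajectories — the normalizer of R²."""
    return 0.5 * (float(np.var(empirical.var_y)) + float(np.var(empirical.cov_ye)))


def fit_model(
    variant: ModelVariant | str,
    empirical: TrajectoryStatistics,
    family: MeanFamily,
    plant: PlantParameters | None = None,
    delay: float = 0.004,
    n_starts: int = 8,
    seed: int = 0,
    n_obs: int = 6,
    k_A_fixed: float | None = None,
) -> FitResult:
    """Fit a model variant by bounded multi-start local optimization.

    Starts are a seeded Latin-hypercube over the box bounds plus one start
    at the box center; each runs L-BFGS-B with numerical gradients.  The
    best converged minimum is returned.
    """
    if isinstance(variant, str):
        variant = model_variant(variant, k_A_fixed=k_A_fixed)
    engine = PredictionEngine(family, plant, delay)
    lo = np.array([PARAM_BOUNDS[p][0] for p in variant.free])
    hi = np.array([PARAM_BOUNDS[p][1] for p in variant.free])

    # optimize on the unit box so the gain and the noise coefficients see
    # comparable finite-difference steps
    def fun(u):
        x = lo + np.clip(u, 0.0, 1.0) * (hi - lo)
        return objective_mse(variant.full_params(x), empirical, engine)

    # data-informed starts: the end-point variance is dominated by the
    # accumulating noise, so sqrt(var_end)/A_bar seeds k_A near its basin;
    # the loop gain is swept coarsely because its basin is narrow
    k_A0 = float(np.clip(np.sqrt(max(empirical.var_y[-1], 0.0)) / max(empirical.A_bar, 1e-9),
                         *PARAM_BOUNDS["k_A"]))
    informed = []
    for g0 in (60.0, 160.0, 260.0, 340.0):
        p0 = {"k_A": k_A0, "k_ON": 0.01, "k_PBN": 0.02, "g": g0}
        informed.append([(p0[p] - PARAM_BOUNDS[p][0]) / (PARAM_BOUNDS[p][1] - PARAM_BOUNDS[p][0])
                         for p in variant.free])
    sampler = qmc.LatinHypercube(d=len(variant.free), seed=seed)
    n_lhs = max(n_starts - 1 - len(informed), 0)
    starts = sampler.random(n_lhs) if n_lhs else np.empty((0, len(lo)))
    starts = np.vstack([np.full(len(lo), 0.5), np.asarray(informed), starts])
    unit_bounds = [(0.0, 1.0)] * len(lo)
    best = None
    for u0 in starts:
        res = optimize.minimize(
            fun, u0, method="L-BFGS-B", bounds=unit_bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-14, "eps": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    # derivative-free polish: the objective is cheap and the simplex step
    # escapes the flat-gradient ridges the quasi-Newton steps can stall on
    polish = optimize.minimize(
        fun, best.x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-16, "maxiter": 2000},
    )
    if polish.fun < best.fun:
        best = polish
    x_best = lo + np.clip(best.x, 0.0, 1.0) * (hi - lo)
    params = variant.full_params(x_best)
    var_tot = _var_tot(empirical)
    mse = float(best.fun)
    r2 = 1.0 - mse / var_tot if var_tot > 0 else float("nan")
    at_bounds = {
        p: bool(np.isclose(v, PARAM_BOUNDS[p][0]) or np.isclose(v, PARAM_BOUNDS[p][1]))
        for p, v in zip(variant.free, x_best)
    }
    return FitResult(
        variant=variant.name,
        params=params,
        mse=mse,
        var_tot=var_tot,
        r2=r2,
        aic=aic(mse, variant.n_par, n_obs),
        n_par=variant.n_par,
        n_obs=n_obs,
        success=bool(best.success),
        n_starts=n_starts,
        seed=seed,
        at_bounds=at_bounds,
    )


def aic(mse: float, n_par: int, n_obs: int = 6) -> float:
    """Akaike information criterion ``N_obs·ln(MSE) + 2·N_par``.

    ``mse = 0`` (an exact fit) returns −inf as a sentinel.
    """
    if mse < 0:
        raise ValueError("mse must be >= 0")
    if mse == 0:
        return float("-inf")
    return n_obs * math.log(mse) + 2 * n_par


def classify_delta_aic(delta: float) -> str:
    """Empirical-support class of a ΔAIC value (Burnham–Anderson bands)."""
    if delta < 2:
        return "substantial"
    if delta < 4:
        return "intermediate"
    if delta <= 7:
        return "considerably less"
    if delta <= 10:
        return "intermediate"
    return "essentially none"


def delta_aic_and_support(fits: dict[str, "FitResult | float"]) -> pd.DataFrame:
    """ΔAIC (relative to the best model) and support class per variant."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    aics = {k: (v.aic if isinstance(v, FitResult) else float(v)) for k, v in fits.items()}
    best = min(aics.values())
    rows = [
        {"variant": k, "aic": a, "delta_aic": a - best, "support": classify_delta_aic(a - best)}
        for k, a in aics.items()
    ]
    return pd.DataFrame(rows).set_index("variant")


def one_sample_t(values, popmean: float = 0.0) -> dict:
    """One-sample t test summary (t, df, p, mean, sd)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return {"t": float("nan"), "df": n - 1, "p": float("nan"), "mean": mean, "sd": sd,
                "undefined": True}
    from scipy.stats import t as tdist

    t_stat = (mean - popmean) / (sd / math.sqrt(n))
    p = 2 * tdist.sf(abs(t_stat), n - 1)
    return {"t": float(t_stat), "df": n - 1, "p": float(p), "mean": mean, "sd": sd,
            "undefined": False}


def contrast_conditions(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    parameters: tuple[str, ...] = ("k_A", "k_PBN", "g"),
    subject_col: str = "subject",
    condition_col: str = "condition",
) -> dict:
    """Paired within-subject contrasts of fitted parameters between two
    conditions (``a − b``), with one-sample t statistics on the paired
    differences and Pearson correlations between parameter effects.
    """
    a = table[table[condition_col] == condition_a].set_index(subject_col)
    b = table[table[condition_col] == condition_b].set_index(subject_col)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("conditions must share the same subjects (paired design)")
    a = a.sort_index()
    b = b.sort_index()
    diffs = pd.DataFrame({p: a[p] - b[p] for p in parameters})
    summary = {p: one_sample_t(diffs[p].to_numpy()) for p in parameters}
    corr = diffs.corr(method="pearson")
    return {"differences": diffs, "summary": summary, "correlations": corr,
            "pair": (condition_a, condition_b)}
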