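# saccnoise

Stochastic modeling of the **inter-trial variability of saccade
trajectories**: where does the trial-to-trial scatter of rapid eye movements
come from, and how much of it is kept in check by an internal feedback loop?

The package is written for oculomotor and motor-control researchers who want
to decompose measured variance/covariance trajectories of horizontal
saccades into physiologically interpretable noise components, or to study
how such a decomposition behaves on fully synthetic data with known ground
truth.

## The model

Eye position `y(t)` is generated by a linear chain (all signals in degrees
and seconds):

* a premotor burst neuron (PBN) emitting the velocity command `C2(t)`,
  enclosed in an internal feedback loop — a delayed integrator with gain
  `g` (1/s) and delay `Δt = 4 ms`;
* the classical pulse-step superposition building the oculomotor command
  `C3(t) = τ1·C2(t) + ∫C2`;
* a third-order low-pass plant `1/((τ1 s+1)(τ2 s+1)(τ3 s+1))` with
  `τ1 = 223 ms, τ2 = 14 ms, τ3 = 4 ms`.

Three independent noise sources perturb the chain:

| source | entry point | structure | trajectory signature |
|---|---|---|---|
| planning (`k_A`) | planned amplitude | `A ~ N(Ā, k_A²Ā²)` | S-shaped, correlation with endpoint ≡ 1 |
| ON motor noise (`k_ON`) | after the pulse-step | white, SD ∝ `|C3(t)|` | S-shaped, monotone |
| PBN premotor noise (`k_PBN`) | inside the loop | white, SD ∝ `|C2(t)|` | bell-shaped: rises, then suppressed by feedback |

For each source the package computes the variance trajectory
`var_y(t)` and the covariance-with-endpoint trajectory `cov_ye(t)` in closed
form, e.g. for loop-injected noise

```
var_y(t)  = ∫₀ᵗ Q_PBN(τ)·q²(t−τ) dτ,
cov_ye(t) = ∫₀ᵗ Q_PBN(τ)·q(t−τ)·q(D−τ) dτ,
```

with `q = n ⊛ p` the loop→eye impulse response and the power density
`Q_PBN` solving the Volterra integral equation
`Q = k²(C̄2² + ∫Q·m²)` (the noise feeds back onto its own scaling signal).
The correlation trajectory `ρ_ye(t) = cov_ye/√(var_y·var_y(D))` and its
90%-crossing time `P_ρ=0.9` summarize how early the endpoint becomes
predictable. Free parameters `[k_A, k_ON, k_PBN, g]` are fitted to measured
trajectories by bounded multi-start least squares and compared across
reduced model variants with `AIC = N_obs·ln(MSE) + 2·N_par`.

A Monte-Carlo generator (`saccnoise.synth`) produces trial ensembles from
exactly this generative model, sharing its discrete-time conventions with
the analytic propagation, so simulation and theory agree to sampling error —
the backbone of the test suite.

## Worked example

```python
import numpy as np
from saccnoise import (MainSequenceModel, MeanFamily, PredictionEngine,
                       generate_ensemble, normalize_and_resample, fit_model,
                       correlation_trajectory)

# simulate 2000 control-condition trials (Ā = 10.1 deg, g = 240/s)
ens = generate_ensemble(2000, "control", seed=42)
stats = normalize_and_resample(ens)           # 100-sample var/cov trajectories
_, p09 = correlation_trajectory(stats)

# fit the 3-parameter model without ON noise
ms = MainSequenceModel()
family = MeanFamily.from_model(ms, stats.A_bar)
fit = fit_model("no_ON", stats, family, seed=1)
print(f"P(rho=0.9) = {p09:.0f}%  fitted: k_A={fit.params['k_A']:.3f} "
      f"k_PBN={fit.params['k_PBN']:.3f} g={fit.params['g']:.0f}/s R2={fit.r2:.3f}")
```

prints

```
P(rho=0.9) = 66%  fitted: k_A=0.105 k_PBN=0.026 g=205/s R2=0.992
```

i.e. the correlation trajectory reaches 0.9 at ~66% of the saccade, and the
fit recovers the generating noise coefficients (`k_A = 0.106`,
`k_PBN = 0.028`) and feedback gain (240/s, biased low by ~15% through the
per-trial time normalization — see `docs/methods.md`) with `R² ≈ 0.99`.

The same workflow is available from the shell:

```
saccnoise simulate --preset control --n-trials 2000 --seed 42 --out trials.csv
saccnoise stats --trials trials.csv --out stats.csv
saccnoise pipeline --out run1 --seed 42       # all three conditions + fits + AIC
saccnoise contrast --a ipsiversive --b control
```

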