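# Methods

This note documents the model, the numerical conventions, the synthetic-data
generator, and the design choices made where more than one reasonable option
existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

Horizontal saccades are generated by a linear time-invariant chain: a
premotor burst neuron (PBN) whose output `C2(t)` (deg/s) is controlled by an
internal feedback loop (delayed integrator, gain `g` in 1/s, delay
`Δt = 4 ms`); the pulse-step superposition `C3 = τ1·C2 + ∫C2` converting the
burst into the oculomotor-neuron command (deg); and a third-order low-pass
plant `1/((τ1 s+1)(τ2 s+1)(τ3 s+1))` with `τ1 = 223 ms`, `τ2 = 14 ms`,
`τ3 = 4 ms` producing eye position. The loop integrator sits in the feedback
branch; for the transfer of noise injected at the PBN output only the loop
transfer (product of forward and feedback paths) matters, so the
feedforward-integrator variant would make no difference there and is not
implemented.

Trial-to-trial variability has three independent sources:

1. **Planning noise** — the planned amplitude varies across trials,
   `A ~ Normal(Ā, σ_A²)` with `σ_A = k_A·Ā` (constant coefficient of
   variation, motivated by eccentricity-proportional resolution of
   spatiotopic maps). Each trial follows the mean-trajectory family member
   of its own amplitude, so `var_y = (∂ȳ/∂Ā)²σ_A²` and
   `cov_ye = (∂ȳ/∂Ā)σ_A²`: the implied correlation with the endpoint is 1
   from onset. The amplitude sensitivity is estimated, as in the data
   analysis, by the difference quotient of family members at `Ā ± Δ/2`,
   `Δ = 5 deg`, on the duration-normalized axis.
2. **ON noise** — white Gaussian noise at the oculomotor command with power
   density `Q_ON = k_ON²(C̄3² + var_C3)`; it propagates feedforward through
   the plant only: `var_y(t) = ∫Q_ON(τ)p²(t−τ)dτ`,
   `cov_ye(t) = ∫Q_ON(τ)p(t−τ)p(D−τ)dτ`.
3. **PBN noise** — white Gaussian noise at the burst output with density
   `Q_PBN = k_PBN²(C̄2² + var_C2)`. Because the loop feeds the noise back
   into its own scaling signal, `Q_PBN` solves a linear Volterra equation of
   the second kind, `Q = k²C̄2² + k²∫Q(τ)m²(t−τ)dτ`, solved by forward
   recursion; the eye-position trajectories then use the loop→eye response
   `q = n ⊛ p`. The loop suppresses the DC content of injected noise
   (`∫m dt → 0`), which is why this component's variance trajectory is
   bell-shaped: it rises during the movement and is largely compensated by
   its end.

The three sources are independent, so the total prediction is the
sample-wise sum. Note that `Q_PBN` is *not* quadratic in `k_PBN`: the
self-referential feedback term makes variance scaling super-quadratic at
realistic coefficients (quadratic only as `k → 0`).

## Discrete-time conventions

All convolutions, the loop recursion and the Volterra recursion live on a
uniform grid with step `h = 0.5 ms` (half the 1 kHz data rate). Impulse
responses are stored as **unit-sample responses** — the response of the
discrete-time simulation to an input of value 1 at one sample. A direct
feedthrough (a Dirac delta) appears as a plain coefficient at lag 0
(`m[0] = 1`), and integrals are left-Riemann sums excluding the current
sample. Continuous-time integrals `∫Q·f²` become `Σ Q_i f_u²[k−i]/h`.

In the Volterra recursion the direct-feedthrough term is weighted by `h`
(denominator `1 − k²·m²(0)·h` with `m(0) = 1`), and the tail uses the
continuous values `m_u[i]/h`. This convention is forced by consistency with
the generator: the signal-dependent noise SD scales with the command value
*just before* the current sample's own noise is added, whose variance is
exactly the strictly causal sum. The same regularization is applied to the
pulse-step direct feedthrough (`τ1·δ`) inside `var_C3`; a naive `δ → 1/h`
convention would make the recursion ill-posed for any `k² ≥ h`, and the
package raises an explicit error if configured that way.

Because generator and propagation share these conventions exactly, their
agreement (the Monte-Carlo equivalence suite) holds at matched step.
Convergence toward the continuous-time ideal is slower for the loop-filtered
component: halving the step changes the PBN variance prediction by a few
percent at `g = 240/s` (the explicit-Euler loop recursion error is
`O(g·h)`), versus <2% for the feedforward components. This is a
model-definition choice, not an internal inconsistency, and is covered by a
step-halving test.

Other numerical choices: the plant impulse response uses the exact
partial-fraction expansion (repeated time constants are rejected); forward
simulation of `1/(s(τ2 s+1)(τ3 s+1))` uses a first-order-hold
discretization; the inversion `C2 = τ2τ3·y⃛ + (τ2+τ3)·ÿ + ẏ` uses cascaded
centered differences after an optional zero-phase Gaussian low-pass (3 dB at
100 Hz; σ = 1.33 ms), with the outermost three samples per edge treated as
invalid; the inversion round-trip is verified on a 0.25 ms grid, where
third-order differentiation is accurate to <0.5% of amplitude —
differentiation needs finer sampling than the variance convolutions.
Unstable loop configurations (`g·Δt ≥ π/2`) warn rather than raise, because
the optimizer may probe them; its box bounds (`k ∈ [0,1]`,
`g ∈ [0, 350/s]`) keep fits below the instability at the 4 ms delay.

## Synthetic-data generator

The mean-trajectory family is **self-similar**: `ȳ(t, A) = A·F(t/D(A))`
with `D(A) = D_ref + (A − A_ref)/α` (defaults `D_ref = 40 ms` at
`A_ref = 10 deg`, `α = 0.66 deg/ms`). The velocity shape is a two-piece
power-of-smoothstep bump `v ∝ S7(u)^λ` (S7 the 7th-order smoothstep),
peaking at `1 − decel_fraction = 45%` of the movement; `λ` is solved once so
the reference member integrates to `A_ref` given the reference peak velocity
(430 deg/s), and `λ > 1/2` keeps velocity C² (position C³), as the
third-order inversion requires. Self-similarity makes the amplitude
linearization behind the planning-noise formulas exact on the
duration-normalized axis and implies a realistic saturating peak-velocity
main sequence `Vp(A) = A/(D(A)·∫shape)`.

Noisy trials are simulated by superposition (the chain is linear): the mean
path comes from the family; the noise response propagates through the
discrete loop recursion, pulse-step rule, and plant convolution, with
per-sample noise SD `k·|command|/√h`. Planned amplitudes are drawn
`Normal(Ā, k_A²Ā²)`; motor errors are an independent truncated-normal
target jitter (SD 1 deg, clipped to the 8.5–12.5 deg class). Condition
presets (`control`, `ipsiversive_cFN`, `contraversive_cFN`) carry the
group-mean parameters of the five-macaque cFN-inactivation reference
dataset (`saccnoise.datasets`), including condition-specific main-sequence
shapes. Sessions (`generate_session`) concatenate blocks at several target
eccentricities, which the amplitude-binned empirical family estimation and
the main-sequence fits require.

**Duration convention.** `D(A)` is the full profile support. The
10%-of-peak-velocity detection applied to data truncates the slow
initial/final portions, so detected durations of noise-free synthetic
saccades are ~15–20% shorter than `D(A)`; within the family the detected
deceleration fraction still equals `decel_fraction` exactly (the crossing
offsets scale with the piece lengths). A smooth unimodal profile cannot
simultaneously satisfy amplitude 10 deg, peak velocity 430 deg/s and a
*detected* duration of 40 ms (that combination implies a mean/peak speed
ratio below what any C² unimodal profile attains over its threshold
window); real saccades achieve it through slow glissadic tails that this
family does not model. Tests therefore reference detection to the profile's
own crossing span.

**What the generator does not emulate:** corrective saccades, fixation
drift and blinks, measurement/coil noise, latency jitter, nonlinear burst
saturation, and vertical/oblique components. Passing the equivalence and
recovery suites therefore demonstrates the internal consistency of the
propagation mathematics and the estimation pipeline, not that real saccades
contain only these three noise sources.

## Estimators and their pairing with the theory

Two normalization conventions are implemented. Per-trial warping (each
trial's detected window mapped to 100 samples) mirrors the treatment of
recorded data; fixed-window sampling (all trials at the same absolute times
over `[0, D̄]`) estimates variance at fixed time, the quantity the
convolution formulas predict. The validation harness pairs each noise
source with its matching estimator — planning with per-trial warping (the
axis of the difference quotient), ON/PBN with the fixed window — and passes
the generator-known movement windows: threshold-detection timing jitter
imposes a variance floor near 1e-7 deg², which would swamp the planning
variance at `k_A = 0.01` (of order 1e-8 deg² early in the movement) while
being irrelevant at behavioral noise levels. Resampling is linear for
stochastic traces (spline overshoot inflates variance) and cubic for smooth
ones (linear interpolation leaves an error floor).

Fitting minimizes `MSE = ½(⟨Δvar²⟩ + ⟨Δcov²⟩)` over the 100 samples with
L-BFGS-B on a unit-scaled box, multi-start (data-informed starts seed `k_A`
from the endpoint variance and sweep the gain coarsely — the likelihood has
a spurious basin near `k_A = 0` — plus Latin-hypercube extras) and a
Nelder-Mead polish. `R² = 1 − MSE/VAR_tot` with `VAR_tot` the mean of the
across-sample variances of the two fitted trajectories (the literal reading
of the definition). `AIC = N_obs·ln(MSE) + 2·N_par` with the conservative
`N_obs = 6`; support classes: ΔAIC < 2 substantial, 4–7 considerably less,
> 10 essentially none, gaps labeled intermediate. With no PBN noise the
gain is unobservable and drops from the parameter count.

Noiseless self-recovery is exact to <1%. On stochastic tables
(2000 trials, control parameters) recovery depends on the estimator: with
generator-known windows the median errors are ~0.2% (`k_A`), ~1% (`k_PBN`)
and ~0.3% (`g`); with detection-based per-trial windows, ~2.5%, ~7% and
~20% — the gain soaks up the systematic distortion that duration jitter
mixes into the warped variance. Planning and ON noise produce nearly
identical trajectory shapes, so the full model is not identifiable along a
`(k_A, k_ON)` ridge; this is reproduced as a documented property, and the
3-parameter no-ON variant (planning and ON merged into "accumulating
noise") is the workhorse model.

## Sizes and tolerances used by the validation suites

Equivalence sweeps use 2000 trials (4000 at the largest PBN coefficient,
where the multiplicative feedback makes the variance estimator heavy-tailed)
and compare at 3 moment-based standard errors — computed from empirical
fourth moments, so heavy-tailed configurations get honestly wider bands —
requiring agreement at ≥95% of the 100 samples. Parameter recovery uses 10
replicates of 2000 trials. The replica pipeline defaults to 400 trials per
target eccentricity per condition. These sizes give comfortable statistical
resolution for every asserted property while keeping the full suite in the
low minutes on one CPU.

## Known limitations

* The planning linearization (and hence the fits) assumes small `k_A`;
  at coefficients ≫ 0.2 the family curvature in amplitude is no longer
  negligible.
* The `Q_PBN` recursion diverges within the movement when
  `k_PBN²·∫m_c² ≳ 1` (e.g. `k_PBN = 0.1` at `g = 240/s`); simulation and
  recursion still agree in expectation, but such regimes are far outside
  the physiological range.
* Analytic predictions are computed on the absolute-time grid and resampled;
  the per-trial warped statistics of mixed-source ensembles therefore carry
  a small systematic mismatch that biases the fitted gain low (documented
  above), exactly as a real-data analysis warped the same way would.
* The mixed ON×PBN cross term (`var_C3` inside `Q_ON`) depends on the
  regularization of the pulse-step direct feedthrough and does not converge
  under step refinement; it vanishes in the fitted no-ON model and in all
  single-source analyses.
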