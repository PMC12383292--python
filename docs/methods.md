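# Methods

## Model

`bdchain` simulates and analyses a nonautonomous stochastic delay system
for a three-species food chain (prey `x1`, predator `x2`, top predator
`x3`) with Beddington–DeAngelis (BD) trophic interactions:

```
dx1 = x1 [ r1(t) − a11(t) x1 − a12(t) x2 / (1 + β1(t) x1 + γ1(t) x2) ] dt + σ1(t) x1 dB1
dx2 = x2 [ −r2(t) + a21(t) x1(t−τ1) / (1 + β1(t) x1(t−τ1) + γ1(t) x2(t−τ1))
           − a22(t) x2 − a23(t) x3 / (1 + β2(t) x2 + γ2(t) x3) ] dt + σ2(t) x2 dB2
dx3 = x3 [ −r3(t) + a32(t) x2(t−τ2) / (1 + β2(t) x2(t−τ2) + γ2(t) x3(t−τ2))
           − a33(t) x3 ] dt + σ3(t) x3 dB3
```

with positive history functions `φ_i` on `[−τ, 0]`, `τ = max(τ1, τ2)`.
The BD response `a·u/(1+βu+γv)` saturates in the consumed species and is
damped by interference among consumers; the energy-transfer terms act
with gestation delays `τ1` (prey → predator) and `τ2` (predator → top
predator), and their denominators use the delayed densities of **both**
interacting species — no mixed current/delayed variant is offered.
`B1..B3` are independent standard Brownian motions (the noise model is
diagonal and uncorrelated; unbounded Wiener increments are used even
though a bounded-noise reading is sometimes attached to such models —
a literal bound on Brownian motion cannot hold).

Every coefficient is a strictly positive, bounded function of time; the
implemented families are constants and sinusoids `c + b·sin(ωt)` /
`c + b·cos(ωt)` (seasonality, period `2π/ω`, default `ω = π`), plus
arbitrary callables.  Noise intensities are additionally allowed to be
identically zero so the deterministic limit is a proper member of the
model family; interaction coefficients may be zeroed for decoupling
experiments (the prey equation then reduces to a scalar stochastic
logistic equation, which is exactly what the cross-validation oracle
exploits).

## Analytic criteria

The criteria engine consumes only the extrema `g^m = sup g`,
`g^l = inf g` over `[0, ∞)`, computed **exactly** as `c ± |b|` for the
sinusoid families (grid scans are used for generic callables and as an
independent check).  It evaluates:

* **Persistence bounds.** Upper bounds
  `M1 = (r1^m − 0.5(σ1^l)²)/a11^l`,
  `M2 = (−r2^l + a21^m/β1^l − 0.5(σ2^l)²)/a22^l`,
  `M3 = (−r3^l + a32^m/β2^l − 0.5(σ3^l)²)/a33^l`, and chained lower
  bounds `m1, m2, m3` (e.g. `m1 = (r1^l − a12^m/γ1^l − 0.5(σ1^m)²)/a11^m`;
  `m2` uses `m1, M1, M2`; `m3` uses `m2, M2, M3`), together with the six
  sufficient conditions H1–H6 reported as `(lhs, rhs, margin)` triples.
  Bounds are returned even when non-positive (with warnings), since the
  sufficient conditions may simply fail; empirical band checks should
  use `max(m_i, 0)`.
* **Attractivity coefficients.** For positive weights `λ1..λ3`, the
  Lyapunov decay rates `A, B, C` with squared denominators
  `D1² = (1+β1^l m1+γ1^l m2)²`, `D2² = (1+β2^l m2+γ2^l m3)²`, and the
  sufficient condition H7: `A, B, C > 0` for pathwise convergence of any
  two solutions.  The coefficients are homogeneous of degree 1 in the
  weights; `search_weights` grid-searches `λ2, λ3` (with `λ1 = 1`) for a
  sign certificate.  Default weights are `(1, 1, 1)` — no specific
  choice is canonical.  When a zero interaction coefficient makes a
  denominator term vanish the term contributes nothing even if the
  chained `m` bounds would make `D` non-positive; a non-positive `D`
  under a non-zero numerator flags the result as degenerate.
* **Moment bounds.** For `p > 1`,
  `L1(p) = [1 + r1^m p + 0.5 p²(σ1^m)²]^{p+1} / ((p+1)^{p+1} (a11^l)^p)`
  and the analogous `G1(p), F1(p)` with net intake terms
  `−r2^l p + (a21^m/β1^l) p` and `−r3^l p + (a32^m/β2^l) p`; the
  long-run contract values are `L = 1.5·L1` etc., bounding
  `E x_i^p(t)` for large `t`.

### Evaluation-convention caveats

The published worked arithmetic for the three reference
parameterizations mixes two conventions — sometimes the sinusoid midline
`c`, sometimes the exact extrema `c ± |b|`.  This package always takes
the literal sup/inf reading.  Consequences, all reproduced by
`bdchain check`:

* the exact `M1` for the baseline model is 29.6 (the midline evaluation
  gives ≈4.9), which inflates the H5/H6 denominators; H6 then fails by
  a hair (margin ≈ −1.0e−3) and the `λ=(1,1,1)` coefficients `A, B, C`
  come out negative, even though the simulated system is empirically
  both persistent and pathwise attractive — the conditions are
  sufficient, not necessary;
* the printed definition of `m3` uses `(σ3^l)²` where the parallel
  `m1, m2` terms use `(σ_i^m)²` and H6 uses `(σ3^m)²`.  The
  `sigma_convention` flag selects `"printed"` (default, verbatim) or
  `"sup"` (σ3^m uniformly); it only moves `m3`.

## Numerical scheme

Strong order-1 Milstein on a fixed grid (`x_i' = x_i + f_i Δt + σ_i x_i
ΔB_i + 0.5 σ_i² x_i (ΔB_i² − Δt)`, no Lévy-area terms for diagonal
noise), with an Euler–Maruyama fallback.  Delays must be integer
multiples of `Δt` (within 1e−9) and are resolved by exact index shifts;
an optional linear-interpolation mode accepts misaligned delays.
Coefficients are pre-evaluated on the whole grid once per run.
A single integer seed generates the three independent increment streams
(`numpy.random.default_rng`); paths are reusable objects, so paired runs
(common random numbers) and coarsenings (summing groups of increments)
are exactly the same realization.

The exact solution stays positive but the explicit scheme can
overshoot.  Default policy: clamp at `1e−12` and count interventions
(`clamp_count`, exposed in trajectories and metadata); `reject` aborts
instead.  All three reference parameterizations run clamp-free at
`Δt = 0.01`.

## Validation oracles

* **Pathwise closed form.** The scalar stochastic logistic equation
  `dN = N[(a − bN)dt + α dB]` has the explicit solution
  `N(t) = exp{∫(a − α²/2)ds + ∫α dB} / (1/N0 + ∫ b·exp{…} ds)`.
  Both integrals are discretized Itô-consistently (left-point /
  left-Riemann) on the grid of a given Brownian path, so the formula and
  the scheme approximate the same realization.  Embedding the logistic
  equation as the decoupled prey species exercises the full integrator.
* **Strong-order study.**  Mean endpoint error at `T = 1` versus the
  closed form as `Δt` halves through `2⁻⁷..2⁻¹⁰` over 200 common paths.
  The left-Riemann reference itself carries an `O(Δt)` error of similar
  size to the Milstein error, which floors the measurement if both use
  the same grid; the reference is therefore evaluated at `2⁻¹⁵` on the
  same path and the increments are coarsened for each Milstein level.
  Observed order ≈ 0.97.
* **Deterministic limit.**  A classical RK4 integrator for the `σ ≡ 0`
  delay system (exact-index delay lookup at grid times, linear
  interpolation at half-step stages).  At `Δt = 1e−3`, `T = 20` the two
  independent integrators agree within 3e−4 relative on the baseline
  parameterization.

## Synthetic data and presets

The three reference parameterizations are committed twice — as code and
as a plain-text transcription table (`data/preset_coefficients.csv`)
audited by the test suite.  All use `τ1 = 6`, `τ2 = 8`, constant history
0.5, `Δt = 0.01`.  `random_model` draws sinusoid parameterizations
around the baseline magnitudes (log-uniform midline jitter ×e^±0.35,
amplitude ratios shrunk by a uniform factor) and rejection-samples until
a requested condition profile holds (`persistent` additionally proposes
small `σ3` midlines in [0.01, 0.06], since H6 is the binding constraint;
`h3_violated` proposes `a32` midlines in [5e−4, 3e−3]).  The generator
emulates the seasonal-coefficient structure of the study systems only;
it does not emulate demographic noise, parameter uncertainty or
observation error, so passing tests certify the formulas and the
integrator, not fit to field data.

## Empirical diagnostics and default protocol sizes

`tail_extrema` summarizes the last fraction `w` of a run (default 0.25);
empirical persistence checks compare against `[max(m_i,0)·(1−s),
M_i·(1+s)]` with slack `s = 0.1` because the analytic bounds are
asymptotic.  `extinction_time` reports the first time a species stays
below a threshold (default 1e−3) for a full dwell window (default 10
time units) — the dwell suppresses transient dips.  `pair_divergence`
requires a shared grid and Brownian path and reports tail sup-norm
differences and their ratio to the initial separation.

Protocol sizes used by the test suite: persistence run `T = 100`,
extinction run `T = 200`, paired runs `T = 100` (tail fraction 0.25),
strong-order study 200 paths, moment Monte-Carlo 40 paths at `T = 20`.

## Known limitations

* The conditions H1–H7 are sufficient only.  The non-attractive
  reference parameterization (H7 fails for all searched weights)
  nevertheless synchronizes pathwise under common random numbers — its
  strong self-limitation contracts trajectories within `t ≈ 20`.
  Non-convergence of that model is observable only between runs driven
  by independent noise realizations, a protocol this package
  deliberately does not use for its attractivity probe (independent
  noise cannot distinguish convergence from its absence).
* Explicit scheme only: no adaptive stepping, no positivity-preserving
  (Lamperti/balanced) variants, no jump or telegraph noise.
* Sup/inf over `[0, ∞)` for generic callables is approximated by a
  finite grid scan and is the caller's responsibility to window
  correctly.
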