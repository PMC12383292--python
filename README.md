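# bdchain

Simulation and criteria toolkit for a **nonautonomous delayed stochastic
three-species food chain with Beddington–DeAngelis functional response**.

The model tracks prey `x1`, predator `x2` and top predator `x3` under
seasonal (sinusoidal) demographic rates, multiplicative environmental
noise `σ_i(t) x_i dB_i(t)`, gestation delays `τ1, τ2` in the trophic
transfer terms, and BD interactions `a·u/(1+βu+γv)` that saturate in the
consumed species and are damped by consumer interference:

```
dx1 = x1 [ r1 − a11 x1 − a12 x2/(1+β1 x1+γ1 x2) ] dt + σ1 x1 dB1
dx2 = x2 [ −r2 + a21 x1(t−τ1)/(1+β1 x1(t−τ1)+γ1 x2(t−τ1)) − a22 x2
           − a23 x3/(1+β2 x2+γ2 x3) ] dt + σ2 x2 dB2
dx3 = x3 [ −r3 + a32 x2(t−τ2)/(1+β2 x2(t−τ2)+γ2 x3(t−τ2)) − a33 x3 ] dt + σ3 x3 dB3
```

It is aimed at theoretical ecologists and stochastic-dynamics
practitioners who want to (a) simulate such systems reproducibly with a
strong order-1 Milstein scheme, and (b) evaluate the algebraic
sufficient conditions that govern their long-run behaviour:

* **uniform persistence** — explicit bounds `m_i ≤ x_i(t) ≤ M_i`
  (for large `t`) built from the coefficient extrema `g^m = sup g`,
  `g^l = inf g`, with conditions H1–H6 reported as signed margins;
* **global attractivity** — Lyapunov decay coefficients `A, B, C`
  (condition H7: all positive) certifying pathwise convergence of any
  two solutions, probed numerically with common-random-number paired
  runs;
* **moment bounds** — `E x_i^p(t) ≤ 1.5·L1(p)` etc. for `p > 1`.

Everything is cross-validated against independent oracles: the scalar
stochastic logistic equation's pathwise closed form, and an RK4
integrator for the deterministic (`σ ≡ 0`) delay system.  See
`docs/methods.md` for the formulas, numerical choices and known caveats.

## Worked example

```python
from bdchain import (preset, simulate, SimulationConfig, tail_extrema,
                     persistence_bounds, check_conditions)

base = preset("model33")              # baseline seasonal parameterization
bounds = persistence_bounds(base.params)
print(f"m1 = {bounds.m1:.2f}, M1 = {bounds.M1:.2f}")

report = check_conditions(base.params)
print("H3 margin:", round(report["H3"].margin, 4),
      "satisfied:", report["H3"].satisfied)

cfg = SimulationConfig(dt=0.01, horizon=100.0, seed=1)
traj = simulate(base.params, base.history, cfg)
tail = tail_extrema(traj, fraction=0.5)
for i in range(3):
    print(f"x{i+1} tail band: [{tail.minima[i]:.3f}, {tail.maxima[i]:.3f}]")
```

prints

```
m1 = 1.91, M1 = 29.60
H3 margin: 8.0731 satisfied: True
x1 tail band: [1.790, 19.232]
x2 tail band: [1.476, 3.738]
x3 tail band: [0.902, 1.415]
```

`m1 = 1.91` is the analytic asymptotic floor for the prey density and
`H3 > 0` says the top predator's saturated intake ceiling `a32^m/β2^l`
exceeds its mortality load — a persistence requirement.  The simulated
tail bands confirm all three species fluctuate inside a positive band
over the second half of the run.  Cutting the energy-conversion rate to
`a32 = 0.001 + 0.0005 sin πt` (`preset("model35")`) flips H3 negative
(margin ≈ −0.0027) and the simulated top predator drops below 1e−3 for
good within `T = 200` while prey and predator persist.

## Command line

```sh
bdchain check --preset model35            # H1–H7 margins, both sigma conventions
bdchain bounds --preset model33           # M1..M3, m1..m3
bdchain simulate --preset model33 --seed 1 --out run/
bdchain pair --preset model33 --seed 1    # common-noise attractivity probe
bdchain oracle-test --seed 4              # Milstein vs closed-form logistic
bdchain sweep --profile persistent --count 10
```

Model parameterizations can also be given as YAML config files (see
`bdchain.io.write_config` for the schema; unknown keys are errors).

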