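"""Independent reference solutions.

Two oracles validate the stochastic integrator without sharing its code
path:

* the scalar stochastic logistic equation
  ``dN = N[(a(t) - b(t) N) dt + alpha(t) dB]`` has a closed-form positive
  solution; evaluated on the *same* Wiener increments it gives a pathwise
  reference for the Milstein scheme (the prey equation decouples to
  exactly this form when the predation term is switched off);
* a classical fourth-order Runge-Kutta integrator for the sigma=0
  deterministic delay system.

Both use the Ito (left-point) convention so their discretization error is
aligned with the path discretization.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .coefficients import Coefficient, constant
from .integrate import BrownianPath, SimulationConfig, Trajectory
from .model import ModelParameters, as_history, _drift_scalar

__all__ = [
    "LogisticSpec",
    "logistic_closed_form",
    "logistic_embedding",
    "deterministic_reference",
    "strong_convergence_study",
]


def _as_coeff(v: Union[float, Coefficient], name: str,
              allow_zero: bool = False) -> Coefficient:
    if isinstance(v, Coefficient):
        return v
    return constant(float(v), name=name, allow_zero=allow_zero)


@dataclass(frozen=True)
class LogisticSpec:
    """Scalar stochastic logistic equation with positive ``a, b`` and
    noise intensity ``alpha`` (may be zero)."""

    a: Coefficient
    b: Coefficient
    alpha: Coefficient
    N0: float

    def __post_init__(self):
        if self.N0 <= 0.0:
            raise ValueError("N0 must be strictly positive")

    @classmethod
    def make(cls, a, b, alpha, N0: float) -> "LogisticSpec":
        return cls(
            a=_as_coeff(a, "a"),
            b=_as_coeff(b, "b"),
            alpha=_as_coeff(alpha, "alpha", allow_zero=True),
            N0=float(N0),
        )


def logistic_closed_form(
    spec: LogisticSpec, path: BrownianPath, component: int = 0
) -> np.ndarray:
    """Closed-form solution evaluated pathwise on the grid of ``path``.

    N(t) = exp{ I(t) } / ( 1/N0 + int_0^t b(s) exp{ I(s) } ds ),
    I(t) = int_0^t [a - 0.5 alpha^2] ds + int_0^t alpha dB.

    Time integrals are left-Riemann sums on the grid; the stochastic
    integral is the Ito sum ``sum alpha(t_k) dB_k`` over the same
    increments that drive the scheme under test, so the comparison is per
    realization, not in distribution.
    """
    dt = path.dt
    n = path.n_steps
    t_left = np.arange(n) * dt
    a_vals = np.asarray(spec.a(t_left), dtype=float)
    b_vals = np.asarray(spec.b(t_left), dtype=float)
    al_vals = np.asarray(spec.alpha(t_left), dtype=float)
    incr = path.component(component)

    integrand = (a_vals - 0.5 * al_vals**2) * dt + al_vals * incr
    exponent = np.concatenate(([0.0], np.cumsum(integrand)))
    growth = np.exp(exponent)
    denom = 1.0 / spec.N0 + np.concatenate(
        ([0.0], np.cumsum(b_vals * growth[:-1] * dt))
    )
    return growth / denom


def logistic_embedding(spec: LogisticSpec) -> ModelParameters:
    """Embed the scalar logistic equation as species 1 of the food chain.

    All four interaction coefficients are zero, so the prey equation is
    exactly ``dx1 = x1[(a - b x1) dt + alpha dB1]`` while species 2 and 3
    decay independently.  Delays are zero; simulating this model and
    reading species 1 exercises the full integrator code path on an
    equation with a known solution.
    """
    zero = lambda n: constant(0.0, name=n, allow_zero=True)
    one = lambda n: constant(1.0, name=n)
    return ModelParameters(
        r1=spec.a, a11=spec.b, a12=zero("a12"),
        beta1=one("beta1"), gamma1=one("gamma1"), sigma1=spec.alpha,
        r2=one("r2"), a21=zero("a21"), a22=one("a22"), a23=zero("a23"),
        beta2=one("beta2"), gamma2=one("gamma2"), sigma2=zero("sigma2"),
        r3=one("r3"), a32=zero("a32"), a33=one("a33"), sigma3=zero("sigma3"),
        tau1=0.0, tau2=0.0,
    )


def strong_convergence_study(
    spec: LogisticSpec,
    exponents: tuple[int, ...] = (7, 8, 9, 10),
    n_paths: int = 200,
    fine_exponent: int = 15,
    seed: int = 0,
    horizon: float = 1.0,
) -> dict:
    """Empirical strong order of the Milstein scheme on the logistic SDE.

    For each path, the closed form is evaluated on a fine grid
    (``dt = 2**-fine_exponent``) and the Milstein scheme runs on coarsened
    copies of the *same* increments at ``dt = 2**-e`` for each requested
    exponent.  Returns the mean endpoint errors per level and the fitted
    log2-log2 slope (Milstein's strong order is 1 for this diagonal-noise
    problem; the left-Riemann reference itself carries an O(dt_fine)
    error, hence the much finer reference grid).
    """
    from .integrate import SimulationConfig, generate_brownian, simulate

    if fine_exponent < max(exponents):
        raise ValueError("reference grid must be finer than every test grid")
    emb = logistic_embedding(spec)
    n_fine = int(round(horizon * 2**fine_exponent))
    errors: dict[int, list[float]] = {e: [] for e in exponents}
    rng = np.random.default_rng(seed)
    path_seeds = rng.integers(0, 2**31 - 1, size=n_paths)
    for path_seed in path_seeds:
        path = generate_brownian(n_fine, 2.0**-fine_exponent, int(path_seed))
        ref = logistic_closed_form(spec, path)[-1]
        for e in exponents:
            coarse = path.coarsen(2 ** (fine_exponent - e))
            cfg = SimulationConfig(dt=2.0**-e, horizon=horizon, seed=0)
            traj = simulate(emb, (spec.N0, 0.5, 0.5), cfg, brownian=coarse)
            errors[e].append(abs(traj.species(0)[-1] - ref))
    mean_errors = {e: float(np.mean(v)) for e, v in errors.items()}
    dts = np.array([2.0**-e for e in exponents])
    es = np.array([mean_errors[e] for e in exponents])
    order = float(np.polyfit(np.log2(dts), np.log2(es), 1)[0])
    return {"mean_errors": mean_errors, "order": order, "n_paths": n_paths}


def deterministic_reference(
    params: ModelParameters, history, config: SimulationConfig
) -> Trajectory:
    """Classical RK4 solution of the sigma=0 delay system.

    Noise intensities stored in ``params`` are ignored.  Delayed states at
    grid times use the exact stored index; the half-step stages use linear
    interpolation between adjacent stored columns (the histories supply
    values for lags reaching before t=0).  With zero delays the stage's
    own state is used, recovering the plain ODE.
    """
    config.validate()
    hist = as_history(history)
    dt = config.dt
    n = config.n_steps
    tau1, tau2 = params.tau1, params.tau2
    if tau1 < 0 or tau2 < 0:
        raise ValueError("delays must be non-negative")

    times = np.arange(n + 1) * dt
    xs1: list[float] = []
    xs2: list[float] = []
    xs3: list[float] = []

    x0 = np.asarray(hist(0.0), dtype=float)
    if x0.shape != (3,) or np.any(x0 <= 0.0):
        raise ValueError("history must be strictly positive at t=0")
    xs1.append(float(x0[0]))
    xs2.append(float(x0[1]))
    xs3.append(float(x0[2]))

    def lookup(s: float, stage_state):
        """State at absolute time s (s <= current frontier)."""
        if s <= 0.0:
            v = hist(s)
            return float(v[0]), float(v[1]), float(v[2])
        jf = s / dt
        j0 = int(np.floor(jf))
        fr = jf - j0
        if j0 >= len(xs1) - 1:
            # frontier (or beyond by rounding): use latest stage value
            if fr < 1e-9 and j0 == len(xs1) - 1:
                return xs1[j0], xs2[j0], xs3[j0]
            return stage_state
        if fr < 1e-9:
            return xs1[j0], xs2[j0], xs3[j0]
        w = 1.0 - fr
        return (
            w * xs1[j0] + fr * xs1[j0 + 1],
            w * xs2[j0] + fr * xs2[j0 + 1],
            w * xs3[j0] + fr * xs3[j0 + 1],
        )

    def rhs(t: float, state):
        x1, x2, x3 = state
        c = params.evaluate(t)
        if tau1 == 0.0:
            d11, d12 = x1, x2
        else:
            d11, d12, _ = lookup(t - tau1, state)
        if tau2 == 0.0:
            d22, d23 = x2, x3
        else:
            _, d22, d23 = lookup(t - tau2, state)
        return _drift_scalar(c, x1, x2, x3, d11, d12, d22, d23)

    h = dt
    x = (xs1[0], xs2[0], xs3[0])
    for k in range(n):
        t = k * h
        k1 = rhs(t, x)
        x2v = tuple(x[i] + 0.5 * h * k1[i] for i in range(3))
        k2 = rhs(t + 0.5 * h, x2v)
        x3v = tuple(x[i] + 0.5 * h * k2[i] for i in range(3))
        k3 = rhs(t + 0.5 * h, x3v)
        x4v = tuple(x[i] + h * k3[i] for i in range(3))
        k4 = rhs(t + h, x4v)
        x = tuple(
            x[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            for i in range(3)
        )
        xs1.append(x[0])
        xs2.append(x[1])
        xs3.append(x[2])

    return Trajectory(
        times=times,
        states=np.array([xs1, xs2, xs3]),
        dt=dt,
        scheme="rk4",
        seed=None,
        params_hash=params.params_hash(),
        clamp_count=0,
        history_values=x0,
    )
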