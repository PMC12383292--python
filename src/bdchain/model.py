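"""Drift and diffusion of the delayed stochastic food-chain model.

The state is ``x = (x1, x2, x3)``: prey, predator and top-predator
densities.  Each species carries multiplicative environmental noise
``sigma_i(t) x_i dB_i(t)``, and the trophic transfer terms use the
Beddington-DeAngelis response ``a*u / (1 + beta*u + gamma*v)``, which
saturates in the consumed species ``u`` and is damped by interference
among consumers ``v``.  Energy transfer up the chain acts with discrete
delays: the predator gains from prey abundance a gestation lag ``tau1``
ago, the top predator from predator abundance ``tau2`` ago, and the
delayed response denominators use the delayed densities of *both*
interacting species.

Parameter glossary (all time-varying :class:`~bdchain.coefficients.Coefficient`):

==========  ====================================================
``r1``      prey intrinsic growth rate
``r2, r3``  predator / top-predator death rates
``a11..a33``  intraspecific self-limitation (crowding)
``a12, a23``  predation rates
``a21, a32``  energy conversion rates
``beta1, beta2``  handling/digestion saturation of the consumed species
``gamma1, gamma2``  mutual interference among consumers
``sigma1..sigma3``  environmental noise intensities
``tau1, tau2``  gestation delays (time units)
==========  ====================================================
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .coefficients import Coefficient, CoefficientError, constant

__all__ = [
    "COEFF_NAMES",
    "ModelParameters",
    "HistoryFunction",
    "as_history",
    "constant_history",
    "validate_params",
    "bd_term",
    "drift",
    "diffusion",
]

#: Canonical ordering of the 17 coefficient functions.
COEFF_NAMES = (
    "r1", "a11", "a12", "beta1", "gamma1", "sigma1",
    "r2", "a21", "a22", "a23", "beta2", "gamma2", "sigma2",
    "r3", "a32", "a33", "sigma3",
)

HistoryFunction = Callable[[float], np.ndarray]


@dataclass(frozen=True)
class ModelParameters:
    """The full coefficient set of the three-species model."""

    r1: Coefficient
    a11: Coefficient
    a12: Coefficient
    beta1: Coefficient
    gamma1: Coefficient
    sigma1: Coefficient
    r2: Coefficient
    a21: Coefficient
    a22: Coefficient
    a23: Coefficient
    beta2: Coefficient
    gamma2: Coefficient
    sigma2: Coefficient
    r3: Coefficient
    a32: Coefficient
    a33: Coefficient
    sigma3: Coefficient
    tau1: float = 0.0
    tau2: float = 0.0

    def coefficients(self) -> dict[str, Coefficient]:
        return {name: getattr(self, name) for name in COEFF_NAMES}

    def ordered(self) -> tuple[Coefficient, ...]:
        return tuple(getattr(self, name) for name in COEFF_NAMES)

    def evaluate(self, t: float) -> tuple[float, ...]:
        """All 17 coefficient values at time ``t`` in ``COEFF_NAMES`` order."""
        return tuple(c(t) for c in self.ordered())

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def with_zero_noise(self) -> "ModelParameters":
        """The deterministic limit: sigma_i identically zero."""
        zero = lambda n: constant(0.0, name=n, allow_zero=True)
        return self.replace(
            sigma1=zero("sigma1"), sigma2=zero("sigma2"), sigma3=zero("sigma3")
        )

    def params_hash(self) -> str:
        parts = []
        for name, c in zip(COEFF_NAMES, self.ordered()):
            parts.append(
                f"{name}:{c.kind}:{c.midline!r}:{c.amplitude!r}:{c.angular_rate!r}"
            )
            if c.kind == "generic":
                parts.append(getattr(c.func, "__name__", "callable"))
        parts.append(f"tau:{self.tau1!r}:{self.tau2!r}")
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def constant_history(values: Union[float, Sequence[float]]) -> HistoryFunction:
    """Constant positive history ``phi_i(theta) = v_i`` on ``[-tau, 0]``."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = np.full(3, float(arr))
    if arr.shape != (3,):
        raise ValueError("history needs one value per species")
    if np.any(arr <= 0.0):
        raise ValueError("history values must be strictly positive")
    frozen = arr.copy()
    return lambda theta: frozen


def as_history(obj) -> HistoryFunction:
    """Coerce a scalar, length-3 sequence or callable into a history function."""
    if callable(obj):
        return lambda theta: np.asarray(obj(theta), dtype=float)
    return constant_history(obj)


def validate_params(params: ModelParameters) -> list[str]:
    """Report every violated positivity/boundedness constraint.

    An empty list means the parameterization is admissible.  Noise
    intensities may be zero (deterministic limit); every structural
    coefficient must be strictly positive and bounded.
    """
    problems: list[str] = []
    for name in COEFF_NAMES:
        coeff: Coefficient = getattr(params, name)
        try:
            b = coeff.bounds()
        except CoefficientError as exc:
            problems.append(f"{name}: {exc}")
            continue
        if name.startswith("sigma"):
            if b.inf < 0.0:
                problems.append(f"{name} negative")
        elif b.inf <= 0.0:
            problems.append(f"{name} not strictly positive")
    if params.tau1 < 0.0:
        problems.append("tau1 negative")
    if params.tau2 < 0.0:
        problems.append("tau2 negative")
    return problems


def bd_term(a: float, beta: float, gamma: float, u: float, v: float) -> float:
    """Beddington-DeAngelis response ``a*u / (1 + beta*u + gamma*v)``.

    Bounded by ``a/beta`` (saturation in ``u``) and the cross form
    ``a*v/(1+beta*u+gamma*v)`` by ``a/gamma`` for positive densities.
    """
    return a * u / (1.0 + beta * u + gamma * v)


def _drift_scalar(c, x1, x2, x3, d11, d12, d22, d23):
    """Drift kernel on plain floats; ``c`` is the 17-tuple of coefficient
    values at the current time, ``d11/d12`` the delayed (t - tau1) prey and
    predator densities, ``d22/d23`` the delayed (t - tau2) predator and
    top-predator densities."""
    (r1, a11, a12, b1, g1, _s1,
     r2, a21, a22, a23, b2, g2, _s2,
     r3, a32, a33, _s3) = c
    f1 = x1 * (r1 - a11 * x1 - a12 * x2 / (1.0 + b1 * x1 + g1 * x2))
    f2 = x2 * (
        -r2
        + a21 * d11 / (1.0 + b1 * d11 + g1 * d12)
        - a22 * x2
        - a23 * x3 / (1.0 + b2 * x2 + g2 * x3)
    )
    f3 = x3 * (-r3 + a32 * d22 / (1.0 + b2 * d22 + g2 * d23) - a33 * x3)
    return f1, f2, f3


def _check_positive(label: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{label} must be a 3-vector")
    if np.any(arr <= 0.0):
        raise ValueError(f"{label} must be strictly positive, got {arr}")
    return arr


def drift(t: float, x, x_delay1, x_delay2, params: ModelParameters) -> np.ndarray:
    """Deterministic rate of change at time ``t``.

    ``x_delay1`` is the state at ``t - tau1`` and ``x_delay2`` the state at
    ``t - tau2``; the delayed BD denominators use the delayed densities of
    both interacting species.
    """
    xv = _check_positive("state", x)
    d1 = _check_positive("x_delay1", x_delay1)
    d2 = _check_positive("x_delay2", x_delay2)
    c = params.evaluate(t)
    return np.array(
        _drift_scalar(c, xv[0], xv[1], xv[2], d1[0], d1[1], d2[1], d2[2])
    )


def diffusion(t: float, x, params: ModelParameters) -> np.ndarray:
    """Diagonal multiplicative noise amplitude ``sigma_i(t) * x_i``."""
    xv = _check_positive("state", x)
    s = np.array([params.sigma1(t), params.sigma2(t), params.sigma3(t)])
    return s * xv
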