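"""Reference parameterizations and random parameter generation.

Three named presets reproduce the published simulation studies of the
seasonal food chain (all rates are sinusoids with period 2):

* ``model33`` -- the baseline parameterization: all persistence
  conditions that are robust to the evaluation convention hold, and the
  simulated densities fluctuate inside a positive band.
* ``model35`` -- identical to ``model33`` except the energy conversion
  rate ``a32`` of the top predator is cut to ``0.001 + 0.0005 sin(pi t)``,
  violating condition H3; the top predator declines to extinction.
* ``model36`` -- a parameterization that keeps persistence-style
  behaviour but fails the attractivity condition H7; common-noise runs
  from different histories do not converge.

All presets use gestation delays ``tau1 = 6``, ``tau2 = 8``, constant
history 0.5 for every species and step ``dt = 0.01``.

:func:`random_model` draws sinusoid parameterizations around the preset
magnitudes with a prescribed condition profile, for property testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coefficients import make_coefficient
from .integrate import SimulationConfig
from .model import COEFF_NAMES, ModelParameters

__all__ = ["Preset", "PRESET_NAMES", "PRESET_TABLES", "preset", "random_model"]

PRESET_NAMES = ("model33", "model35", "model36")

# symbol -> (kind, midline, amplitude); transcribed from the printed
# coefficient blocks, one entry per factor of the three equations.
_MODEL33 = {
    "r1": ("sine", 5.5, 0.5),
    "a11": ("sine", 1.2, 1.0),
    "a12": ("sine", 0.062, 0.0005),
    "beta1": ("sine", 0.5, 0.1),
    "gamma1": ("sine", 0.11, 0.01),
    "sigma1": ("sine", 0.5, 0.1),
    "r2": ("cosine", 0.005, 0.001),
    "a21": ("sine", 5.5, 0.5),
    "a22": ("cosine", 2.75, 0.25),
    "a23": ("sine", 0.03, 0.004),
    "beta2": ("sine", 1.5, 0.2),
    "gamma2": ("sine", 0.11, 0.01),
    "sigma2": ("sine", 0.2, 0.1),
    "r3": ("sine", 0.002, 0.001),
    "a32": ("sine", 10.0, 0.5),
    "a33": ("cosine", 4.25, 0.2),
    "sigma3": ("sine", 0.15, 0.075),
}

_MODEL35 = dict(_MODEL33, a32=("sine", 0.001, 0.0005))

_MODEL36 = {
    "r1": ("sine", 3.5, 1.5),
    "a11": ("sine", 1.5, 1.0),
    "a12": ("sine", 0.15, 0.1),
    "beta1": ("sine", 2.0, 0.5),
    "gamma1": ("sine", 1.2, 0.5),
    "sigma1": ("sine", 0.5, 0.1),
    "r2": ("cosine", 0.02, 0.01),
    "a21": ("sine", 4.0, 0.5),
    "a22": ("cosine", 1.5, 0.25),
    "a23": ("sine", 0.15, 0.1),
    "beta2": ("sine", 0.25, 0.1),
    "gamma2": ("sine", 2.5, 0.5),
    "sigma2": ("sine", 0.2, 0.1),
    "r3": ("sine", 0.0005, 0.0001),
    "a32": ("sine", 2.0, 0.5),
    "a33": ("cosine", 7.25, 0.25),
    "sigma3": ("sine", 0.015, 0.0075),
}

PRESET_TABLES = {"model33": _MODEL33, "model35": _MODEL35, "model36": _MODEL36}

_TAU1 = 6.0
_TAU2 = 8.0


@dataclass(frozen=True)
class Preset:
    name: str
    params: ModelParameters
    history: tuple[float, float, float] = (0.5, 0.5, 0.5)
    config: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(dt=0.01, horizon=100.0, seed=0)
    )


def params_from_table(
    table: dict[str, tuple[str, float, float]],
    tau1: float = _TAU1,
    tau2: float = _TAU2,
) -> ModelParameters:
    """Build validated parameters from a symbol -> (kind, c, b) table."""
    missing = set(COEFF_NAMES) - set(table)
    if missing:
        raise ValueError(f"table is missing coefficients: {sorted(missing)}")
    coeffs = {
        name: make_coefficient(kind, c, b, name=name)
        for name, (kind, c, b) in table.items()
    }
    return ModelParameters(**coeffs, tau1=tau1, tau2=tau2)


def preset(name: str) -> Preset:
    """One of the three reference parameterizations."""
    if name not in PRESET_TABLES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return Preset(name=name, params=params_from_table(PRESET_TABLES[name]))


_PROFILES = ("persistent", "h3_violated", "unconstrained")


def random_model(seed: int, profile: str = "unconstrained") -> ModelParameters:
    """A random sinusoid parameterization with a prescribed condition profile.

    Coefficients are drawn around the ``model33`` magnitudes (midlines
    jittered by a log-uniform factor, amplitude ratios shrunk at random),
    keeping the formulas in the numerically well-scaled regime of the
    presets.  Proposals are rejection-sampled until the requested profile
    holds (``persistent``: H1-H6 all satisfied; ``h3_violated``: H3 fails
    while H1 holds; ``unconstrained``: first draw).  Deterministic in
    ``seed``.
    """
    from .criteria import check_conditions

    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {_PROFILES}")
    rng = np.random.default_rng(seed)
    cap = 10_000
    for attempt in range(1, cap + 1):
        table = {}
        for name, (kind, c, b) in _MODEL33.items():
            if profile == "h3_violated" and name == "a32":
                c0 = rng.uniform(5e-4, 3e-3)
                b0 = c0 * rng.uniform(0.0, 0.5)
            elif profile == "persistent" and name == "sigma3":
                c0 = rng.uniform(0.01, 0.06)
                b0 = c0 * rng.uniform(0.0, 0.3)
            else:
                c0 = c * float(np.exp(rng.uniform(-0.35, 0.35)))
                b0 = c0 * (b / c) * rng.uniform(0.5, 1.0)
            table[name] = (kind, c0, b0)
        params = params_from_table(table)
        if profile == "unconstrained":
            return params
        report = check_conditions(params)
        if profile == "persistent" and report.all_satisfied:
            return params
        if (
            profile == "h3_violated"
            and not report["H3"].satisfied
            and report["H1"].satisfied
        ):
            return params
    raise RuntimeError(
        f"could not draw a {profile!r} parameterization in {cap} attempts"
    )
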