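"""Time-varying model coefficients and their extrema.

The food-chain model is nonautonomous: every demographic rate is a
continuous, bounded, strictly positive function of time.  Seasonality is
represented by the sinusoid families ``c + b*sin(w*t)`` and
``c + b*cos(w*t)`` (plus constants and an escape hatch for arbitrary
callables).  The persistence and stability criteria never look at a
coefficient pointwise -- they only consume its supremum ``g^m`` and
infimum ``g^l`` over ``[0, inf)``, which for the sinusoid families are
exactly ``c + |b|`` and ``c - |b|``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "KINDS",
    "Coefficient",
    "CoefficientBounds",
    "CoefficientError",
    "make_coefficient",
    "sup_inf",
    "constant",
    "sine",
    "cosine",
]

KINDS = ("constant", "sine", "cosine", "generic")


class CoefficientError(ValueError):
    """A coefficient violates its positivity or boundedness contract."""


@dataclass(frozen=True)
class CoefficientBounds:
    """Supremum/infimum of a coefficient over its scan domain.

    ``method`` records whether the extrema are analytic (exact ``c +- |b|``
    for constant/sinusoid kinds) or a grid scan over a finite window.
    """

    sup: float
    inf: float
    method: str


@dataclass(frozen=True)
class Coefficient:
    """A bounded time-varying coefficient ``g(t)``.

    Instances are normally built through :func:`make_coefficient`, which
    enforces strict positivity (``midline - |amplitude| > 0``).  Direct
    construction skips that check so that diagnostic code
    (:func:`bdchain.model.validate_params`) can inspect invalid inputs.
    """

    kind: str
    midline: float = 0.0
    amplitude: float = 0.0
    angular_rate: float = math.pi
    func: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, compare=False
    )
    period: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise CoefficientError(
                f"coefficient {self.name or '<unnamed>'}: unknown kind {self.kind!r}"
            )
        if self.kind == "generic" and self.func is None:
            raise CoefficientError(
                f"coefficient {self.name or '<unnamed>'}: generic kind needs a callable"
            )

    def __call__(self, t):
        tt = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full(tt.shape, float(self.midline))
        elif self.kind == "sine":
            out = self.midline + self.amplitude * np.sin(self.angular_rate * tt)
        elif self.kind == "cosine":
            out = self.midline + self.amplitude * np.cos(self.angular_rate * tt)
        else:
            out = np.asarray(self.func(tt), dtype=float)
        if np.ndim(t) == 0:
            return float(out)
        return out

    def bounds(
        self,
        window: Optional[tuple[float, float]] = None,
        grid_step: Optional[float] = None,
        method: str = "auto",
    ) -> CoefficientBounds:
        """Sup/inf over ``[0, inf)`` (analytic) or a finite window (grid)."""
        if method not in ("auto", "analytic", "grid"):
            raise ValueError(f"unknown bounds method {method!r}")
        label = self.name or "<unnamed>"
        if self.kind != "generic" and method in ("auto", "analytic"):
            hi = self.midline + abs(self.amplitude)
            lo = self.midline - abs(self.amplitude)
            return CoefficientBounds(sup=hi, inf=lo, method="analytic")
        if self.kind == "generic" and method == "analytic":
            raise CoefficientError(
                f"coefficient {label}: no analytic extrema for generic kind"
            )
        if window is None:
            if self.kind == "generic":
                if self.period is None:
                    raise CoefficientError(
                        f"coefficient {label}: generic kind needs an explicit "
                        "scan window (or a declared period)"
                    )
                window = (0.0, 2.0 * self.period)
            else:
                # two full periods of the sinusoid cover all extrema
                window = (0.0, 4.0 * math.pi / self.angular_rate)
        if grid_step is None:
            if self.kind == "generic":
                raise CoefficientError(
                    f"coefficient {label}: generic kind needs an explicit grid_step"
                )
            grid_step = (window[1] - window[0]) / 2.0e5
        ts = np.arange(window[0], window[1] + 0.5 * grid_step, grid_step)
        vals = np.asarray(self(ts), dtype=float)
        lo = float(vals.min())
        hi = float(vals.max())
        if lo <= 0.0:
            raise CoefficientError(
                f"coefficient {label}: infimum over the scan window is not positive"
            )
        return CoefficientBounds(sup=hi, inf=lo, method="grid")


def make_coefficient(
    kind: str,
    midline: float = 0.0,
    amplitude: float = 0.0,
    angular_rate: float = math.pi,
    func: Optional[Callable] = None,
    period: Optional[float] = None,
    name: str = "",
    allow_zero: bool = False,
) -> Coefficient:
    """Build a validated coefficient.

    For constant/sinusoid kinds strict positivity ``midline - |amplitude| > 0``
    is required; ``allow_zero=True`` relaxes this to non-negativity, which is
    only appropriate for noise intensities (the deterministic sigma=0 limit)
    and for switching interaction terms off in decoupling experiments.
    """
    label = name or "<unnamed>"
    if kind == "constant" and amplitude != 0.0:
        raise CoefficientError(f"coefficient {label}: constant kind with amplitude")
    if kind != "generic":
        lower = midline - abs(amplitude)
        if allow_zero:
            if lower < 0.0:
                raise CoefficientError(
                    f"coefficient {label} is negative: midline - |amplitude| = {lower}"
                )
        elif lower <= 0.0:
            raise CoefficientError(
                f"coefficient {label} is not strictly positive: "
                f"midline - |amplitude| = {lower}"
            )
    return Coefficient(
        kind=kind,
        midline=float(midline),
        amplitude=float(amplitude),
        angular_rate=float(angular_rate),
        func=func,
        period=period,
        name=name,
    )


def sup_inf(
    coeff: Coefficient,
    window: Optional[tuple[float, float]] = None,
    grid_step: Optional[float] = None,
    method: str = "auto",
) -> CoefficientBounds:
    """Sup/inf of a coefficient; see :meth:`Coefficient.bounds`."""
    return coeff.bounds(window=window, grid_step=grid_step, method=method)


def constant(value: float, name: str = "", allow_zero: bool = False) -> Coefficient:
    return make_coefficient("constant", midline=value, name=name, allow_zero=allow_zero)


def sine(midline: float, amplitude: float, name: str = "",
         angular_rate: float = math.pi) -> Coefficient:
    return make_coefficient("sine", midline, amplitude, angular_rate, name=name)


def cosine(midline: float, amplitude: float, name: str = "",
           angular_rate: float = math.pi) -> Coefficient:
    return make_coefficient("cosine", midline, amplitude, angular_rate, name=name)
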