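"""Analytic persistence, attractivity and moment criteria.

Everything here is exact arithmetic on the sup/inf values ``g^m, g^l`` of
the 17 coefficient functions.  Three groups of results:

* uniform-persistence bounds ``M1..M3`` (upper) and ``m1..m3`` (lower),
  with the sufficient conditions H1-H6 that make them positive;
* global-attractivity coefficients ``A, B, C`` from a delay-compensated
  Lyapunov functional, with free positive weights ``lambda_i`` and the
  sufficient condition H7: ``A, B, C > 0``;
* p-th moment bounds ``L1(p), G1(p), F1(p)`` and the long-run contract
  values ``L(p) = 1.5 L1(p)`` etc. with ``E x_i^p(t) <= L(p), G(p), F(p)``.

The published worked numbers for these formulas mix two evaluation
conventions (sometimes the sinusoid midline ``c``, sometimes the exact
extrema ``c +- |b|``); this module always takes the literal sup/inf
reading.  A second, deliberate inconsistency in the source material is
the noise term of ``m3``: the definition block uses ``(sigma3^l)^2``
where the parallel ``m1, m2`` terms use ``(sigma_i^m)^2``.  The
``sigma_convention`` flag reproduces the definition block verbatim
("printed", default) or applies the supremum uniformly ("sup").
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import ModelParameters

__all__ = [
    "PersistenceBounds",
    "Condition",
    "ConditionReport",
    "AttractivityCoefficients",
    "MomentBounds",
    "WeightSearchResult",
    "persistence_bounds",
    "check_conditions",
    "attractivity_coefficients",
    "search_weights",
    "moment_bounds",
]

_CONVENTIONS = ("printed", "sup")


@dataclass(frozen=True)
class PersistenceBounds:
    """Asymptotic density bounds ``m_i <= x_i(t) <= M_i`` (for large t)."""

    M1: float
    M2: float
    M3: float
    m1: float
    m2: float
    m3: float
    sigma_convention: str = "printed"
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("M1", "M2", "M3", "m1", "m2", "m3")}


@dataclass(frozen=True)
class Condition:
    lhs: float
    rhs: float

    @property
    def margin(self) -> float:
        return self.lhs - self.rhs

    @property
    def satisfied(self) -> bool:
        return self.margin > 0.0


@dataclass(frozen=True)
class ConditionReport:
    conditions: dict[str, Condition]
    sigma_convention: str = "printed"

    def __getitem__(self, key: str) -> Condition:
        return self.conditions[key]

    @property
    def all_satisfied(self) -> bool:
        return all(c.satisfied for c in self.conditions.values())

    def as_dict(self) -> dict[str, dict]:
        return {
            name: {
                "lhs": c.lhs,
                "rhs": c.rhs,
                "margin": c.margin,
                "satisfied": c.satisfied,
            }
            for name, c in self.conditions.items()
        }


@dataclass(frozen=True)
class AttractivityCoefficients:
    A: float
    B: float
    C: float
    D1: float
    D2: float
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    degenerate: bool = False

    @property
    def satisfied(self) -> bool:
        """Condition H7: all three Lyapunov decay coefficients positive."""
        return (not self.degenerate) and self.A > 0.0 and self.B > 0.0 and self.C > 0.0


@dataclass(frozen=True)
class MomentBounds:
    p: float
    L1: float
    G1: float
    F1: float

    @property
    def L(self) -> float:
        return 1.5 * self.L1

    @property
    def G(self) -> float:
        return 1.5 * self.G1

    @property
    def F(self) -> float:
        return 1.5 * self.F1


@dataclass(frozen=True)
class WeightSearchResult:
    weights: tuple[float, float, float]
    coefficients: AttractivityCoefficients
    h7_found: bool


def _table(params: ModelParameters) -> dict[str, tuple[float, float]]:
    """name -> (sup, inf) for all 17 coefficients."""
    out = {}
    for name, coeff in params.coefficients().items():
        b = coeff.bounds()
        out[name] = (b.sup, b.inf)
    return out


def persistence_bounds(
    params: ModelParameters, sigma_convention: str = "printed"
) -> PersistenceBounds:
    """Evaluate the six persistence bounds.

    The bounds are returned as computed even when non-positive (the
    sufficient conditions may fail); non-positive entries are flagged in
    ``warnings`` since empirical checks should use ``max(m_i, 0)``.
    ``m2`` chains through ``m1, M1, M2`` and ``m3`` through ``m2, M2, M3``.
    """
    if sigma_convention not in _CONVENTIONS:
        raise ValueError(f"unknown sigma convention {sigma_convention!r}")
    t = _table(params)
    sup = lambda n: t[n][0]
    inf = lambda n: t[n][1]

    M1 = (sup("r1") - 0.5 * inf("sigma1") ** 2) / inf("a11")
    M2 = (-inf("r2") + sup("a21") / inf("beta1") - 0.5 * inf("sigma2") ** 2) / inf("a22")
    M3 = (-inf("r3") + sup("a32") / inf("beta2") - 0.5 * inf("sigma3") ** 2) / inf("a33")
    m1 = (inf("r1") - sup("a12") / inf("gamma1") - 0.5 * sup("sigma1") ** 2) / sup("a11")
    m2 = (
        -sup("r2")
        + inf("a21") * m1 / (1.0 + sup("beta1") * M1 + sup("gamma1") * M2)
        - sup("a23") / inf("gamma2")
        - 0.5 * sup("sigma2") ** 2
    ) / sup("a22")
    s3 = inf("sigma3") if sigma_convention == "printed" else sup("sigma3")
    m3 = (
        -sup("r3")
        + inf("a32") * m2 / (1.0 + sup("beta2") * M2 + sup("gamma2") * M3)
        - 0.5 * s3 ** 2
    ) / sup("a33")

    warnings = tuple(
        f"{name} is not positive ({value:.6g})"
        for name, value in (("M1", M1), ("M2", M2), ("M3", M3),
                            ("m1", m1), ("m2", m2), ("m3", m3))
        if value <= 0.0
    )
    return PersistenceBounds(
        M1=M1, M2=M2, M3=M3, m1=m1, m2=m2, m3=m3,
        sigma_convention=sigma_convention, warnings=warnings,
    )


def check_conditions(
    params: ModelParameters, sigma_convention: str = "printed"
) -> ConditionReport:
    """Evaluate the persistence conditions H1-H6 with margins.

    H5 and H6 are evaluated at the bounds ``m1, m2, M1..M3`` returned by
    :func:`persistence_bounds` under the same sigma convention.  A
    condition is satisfied iff its margin (lhs - rhs) is positive.
    """
    t = _table(params)
    sup = lambda n: t[n][0]
    inf = lambda n: t[n][1]
    b = persistence_bounds(params, sigma_convention)

    conditions = {
        "H1": Condition(lhs=sup("r1"), rhs=0.5 * inf("sigma1") ** 2),
        "H2": Condition(
            lhs=sup("a21") / inf("beta1"),
            rhs=inf("r2") + 0.5 * inf("sigma2") ** 2,
        ),
        "H3": Condition(
            lhs=sup("a32") / inf("beta2"),
            rhs=inf("r3") + 0.5 * inf("sigma3") ** 2,
        ),
        "H4": Condition(
            lhs=inf("r1"),
            rhs=sup("a12") / inf("gamma1") + 0.5 * sup("sigma1") ** 2,
        ),
        "H5": Condition(
            lhs=inf("a21") * b.m1 / (1.0 + sup("beta1") * b.M1 + sup("gamma1") * b.M2),
            rhs=sup("r2") + sup("a23") / inf("gamma2") + 0.5 * sup("sigma2") ** 2,
        ),
        "H6": Condition(
            lhs=inf("a32") * b.m2 / (1.0 + sup("beta2") * b.M2 + sup("gamma2") * b.M3),
            rhs=sup("r3") + 0.5 * sup("sigma3") ** 2,
        ),
    }
    return ConditionReport(conditions=conditions, sigma_convention=sigma_convention)


def attractivity_coefficients(
    params: ModelParameters,
    bounds: Optional[PersistenceBounds] = None,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> AttractivityCoefficients:
    """Lyapunov decay coefficients ``A, B, C`` for given positive weights.

    ``D1 = 1 + beta1^l m1 + gamma1^l m2`` and ``D2 = 1 + beta2^l m2 +
    gamma2^l m3`` are the squared denominators of the interaction terms.
    When the chained lower bounds make a denominator non-positive the
    coefficients are meaningless; the result is then flagged degenerate.
    The coefficients are homogeneous of degree 1 in the weights.
    """
    l1, l2, l3 = (float(w) for w in weights)
    if min(l1, l2, l3) <= 0.0:
        raise ValueError("attractivity weights must be positive")
    if bounds is None:
        bounds = persistence_bounds(params)
    t = _table(params)
    sup = lambda n: t[n][0]
    inf = lambda n: t[n][1]
    M1, M2, M3 = bounds.M1, bounds.M2, bounds.M3
    m1, m2, m3 = bounds.m1, bounds.m2, bounds.m3

    D1 = 1.0 + inf("beta1") * m1 + inf("gamma1") * m2
    D2 = 1.0 + inf("beta2") * m2 + inf("gamma2") * m3
    degenerate = False

    def ratio(numerator: float, dsq_denom: float) -> float:
        # a zero numerator (decoupled interaction) contributes nothing even
        # when the chained lower bounds make the denominator meaningless
        nonlocal degenerate
        if numerator == 0.0:
            return 0.0
        if dsq_denom <= 0.0:
            degenerate = True
            return np.inf
        return numerator / (dsq_denom * dsq_denom)

    A = (
        l1 * inf("a11")
        - ratio(l1 * sup("a12") * sup("beta1") * M2, D1)
        - ratio(l2 * (sup("a21") + sup("a21") * sup("gamma1") * M2), D1)
    )
    B = (
        l2 * inf("a22")
        - ratio(l1 * (sup("a12") + sup("a12") * sup("beta1") * M1), D1)
        - ratio(l2 * sup("a23") * sup("beta2") * M3, D2)
        - ratio(l2 * sup("a21") * sup("gamma1") * M1, D1)
        - ratio(l3 * (sup("a32") + sup("a32") * sup("gamma2") * M3), D2)
    )
    C = (
        l3 * inf("a33")
        - ratio(l2 * (sup("a23") + sup("a23") * sup("beta2") * M2), D2)
        - ratio(l3 * sup("a32") * sup("gamma2") * M2, D2)
    )
    return AttractivityCoefficients(
        A=A, B=B, C=C, D1=D1, D2=D2, weights=(l1, l2, l3), degenerate=degenerate
    )


def search_weights(
    params: ModelParameters,
    bounds: Optional[PersistenceBounds] = None,
    lambda2_grid: Optional[Sequence[float]] = None,
    lambda3_grid: Optional[Sequence[float]] = None,
) -> WeightSearchResult:
    """Grid search over weights (lambda1 normalized to 1).

    Returns the weights maximizing ``min(A, B, C)`` and whether any grid
    point satisfies H7.  The sufficient condition leaves the weights free,
    so failure on a grid is evidence, not proof, that H7 is unattainable.
    """
    if bounds is None:
        bounds = persistence_bounds(params)
    if lambda2_grid is None:
        lambda2_grid = np.logspace(-2, 2, 21)
    if lambda3_grid is None:
        lambda3_grid = np.logspace(-2, 2, 21)

    best: Optional[AttractivityCoefficients] = None
    best_min = -np.inf
    h7_found = False
    for l2 in lambda2_grid:
        for l3 in lambda3_grid:
            coeffs = attractivity_coefficients(params, bounds, (1.0, l2, l3))
            if coeffs.satisfied:
                h7_found = True
            low = min(coeffs.A, coeffs.B, coeffs.C)
            if best is None or low > best_min:
                best_min = low
                best = coeffs
    assert best is not None
    return WeightSearchResult(weights=best.weights, coefficients=best, h7_found=h7_found)


def moment_bounds(params: ModelParameters, p: float) -> MomentBounds:
    """p-th moment bounds for ``p > 1``.

    ``L1(p) = [1 + r1^m p + 0.5 p^2 (sigma1^m)^2]^(p+1) /
    ((p+1)^(p+1) (a11^l)^p)``; ``G1, F1`` replace the growth term with the
    net delayed-intake terms ``-r2^l p + (a21^m/beta1^l) p`` and
    ``-r3^l p + (a32^m/beta2^l) p``.  The long-run contract values are
    ``L(p) = 1.5 L1(p)`` etc.
    """
    if p <= 1.0:
        raise ValueError("moment order p must exceed 1")
    t = _table(params)
    sup = lambda n: t[n][0]
    inf = lambda n: t[n][1]
    denom = (p + 1.0) ** (p + 1.0)

    L1 = (1.0 + sup("r1") * p + 0.5 * p * p * sup("sigma1") ** 2) ** (p + 1.0) / (
        denom * inf("a11") ** p
    )
    G1 = (
        1.0 - inf("r2") * p + (sup("a21") / inf("beta1")) * p
        + 0.5 * p * p * sup("sigma2") ** 2
    ) ** (p + 1.0) / (denom * inf("a22") ** p)
    F1 = (
        1.0 - inf("r3") * p + (sup("a32") / inf("beta2")) * p
        + 0.5 * p * p * sup("sigma3") ** 2
    ) ** (p + 1.0) / (denom * inf("a33") ** p)
    return MomentBounds(p=p, L1=L1, G1=G1, F1=F1)
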