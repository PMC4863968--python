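"""Closed-form algebra of the three-compartment radicalization model.

A well-mixed population splits into a fixed *inflexible* core fraction
``sigma_I`` and a flexible remainder that is either *peaceful* (``sigma_P``)
or *opponent* (``sigma_O``), with ``sigma_I + sigma_P + sigma_O = 1``.
Inflexibles convert opponents back to peaceful at per-encounter rate
``alpha``; opponents convert peaceful agents at rate ``beta``.  Eliminating
``sigma_O`` leaves a single logistic-type (Riccati) ODE for the peaceful
density::

    d(sigma_P)/dt = alpha*sigma_I*(1 - sigma_I - sigma_P)
                    - beta*(1 - sigma_I - sigma_P)*sigma_P
                  = beta*(p1 - sigma_P)*(p2 - sigma_P)

whose two fixed points are ``p1 = 1 - sigma_I`` (opponent-free) and
``p2 = (alpha/beta)*sigma_I`` (coexistence).  The smaller root is stable;
the switch happens at the critical inflexible fraction
``I_c = beta/(alpha + beta)``.  Everything in this module is exact algebra
on those quantities — no integration happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "TOL",
    "ModelParameters",
    "PopulationState",
    "EquilibriumReport",
    "rhs",
    "equilibrium_roots",
    "stability",
    "critical_threshold",
    "min_core_engagement",
    "classify_regime",
]

#: Module-wide absolute tolerance for floating-point comparisons
#: (root coincidence, domain checks).  Override per call where exposed.
TOL = 1e-9


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParameters:
    """Complete mean-field specification of one scenario.

    Parameters
    ----------
    sigma_I : float
        Inflexible (core) population fraction, in [0, 1].
    alpha : float
        Rate per unit time at which encounters with inflexibles turn
        opponents peaceful (>= 0).
    beta : float
        Rate per unit time at which opponents turn peaceful agents into
        opponents (>= 0).
    """

    sigma_I: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        sigma_I = _require_finite("sigma_I", self.sigma_I)
        alpha = _require_finite("alpha", self.alpha)
        beta = _require_finite("beta", self.beta)
        if not 0.0 <= sigma_I <= 1.0:
            raise ValueError(f"sigma_I must lie in [0, 1], got {sigma_I}")
        if alpha < 0.0:
            raise ValueError(f"alpha must be >= 0, got {alpha}")
        if beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {beta}")
        object.__setattr__(self, "sigma_I", sigma_I)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def sigma_S(self) -> float:
        """Flexible (sensitive) fraction, 1 - sigma_I."""
        return 1.0 - self.sigma_I


@dataclass(frozen=True)
class PopulationState:
    """One sample (t, sigma_P, sigma_O) of the population densities."""

    t: float
    sigma_P: float
    sigma_O: float

    def __post_init__(self) -> None:
        t = _require_finite("t", self.t)
        sigma_P = _require_finite("sigma_P", self.sigma_P)
        sigma_O = _require_finite("sigma_O", self.sigma_O)
        if t < 0.0:
            raise ValueError(f"t must be >= 0, got {t}")
        if sigma_P < 0.0 or sigma_O < 0.0:
            raise ValueError(
                f"densities must be >= 0, got sigma_P={sigma_P}, sigma_O={sigma_O}"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "sigma_P", sigma_P)
        object.__setattr__(self, "sigma_O", sigma_O)

    def check_closure(self, sigma_I: float, tol: float = TOL) -> None:
        """Raise if sigma_I + sigma_P + sigma_O deviates from 1 beyond *tol*."""
        total = sigma_I + self.sigma_P + self.sigma_O
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"densities do not close: sigma_I + sigma_P + sigma_O = {total!r}"
            )


@dataclass(frozen=True)
class EquilibriumReport:
    """Fixed points, eigenvalues and regime classification of one scenario.

    ``p2`` (and the eigenvalues) are ``nan`` in the degenerate beta = 0
    limit, where the dynamics reduce to pure exponential decay of the
    opponent density and only ``p1`` survives as a fixed point.
    """

    p1: float
    p2: float
    lambda1: float
    lambda2: float
    stable_root: str  # "p1" | "p2" | "marginal"
    sigma_P_eq: float
    sigma_O_eq: float
    I_c: float
    regime: str  # "case1" | "case2" | "case3"
    thwarted: bool
    marginal: bool = False
    degenerate_beta0: bool = field(default=False, repr=False)

    def as_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "stable_root": self.stable_root,
            "sigma_P_eq": self.sigma_P_eq,
            "sigma_O_eq": self.sigma_O_eq,
            "I_c": self.I_c,
            "regime": self.regime,
            "thwarted": self.thwarted,
            "marginal": self.marginal,
        }


def rhs(params: ModelParameters, sigma_P: float, *, tol: float = TOL) -> float:
    """Time derivative of the peaceful density at ``sigma_P``.

    Evaluates ``alpha*sigma_I*(1 - sigma_I - sigma_P)
    - beta*(1 - sigma_I - sigma_P)*sigma_P``, which factors as
    ``beta*(p1 - sigma_P)*(p2 - sigma_P)``.

    Raises
    ------
    ValueError
        If ``sigma_P`` lies outside the physical domain
        [0, 1 - sigma_I] beyond *tol*.
    """
    sigma_P = float(sigma_P)
    if sigma_P < -tol or sigma_P > params.sigma_S + tol:
        raise ValueError(
            f"sigma_P={sigma_P} outside physical domain [0, {params.sigma_S}]"
        )
    sigma_O = 1.0 - params.sigma_I - sigma_P
    return params.alpha * params.sigma_I * sigma_O - params.beta * sigma_O * sigma_P


def equilibrium_roots(params: ModelParameters) -> tuple[float, float]:
    """Fixed points (p1, p2) of the peaceful density.

    ``p1 = 1 - sigma_I`` is the opponent-free root; ``p2 =
    (alpha/beta)*sigma_I`` is the coexistence root and may exceed 1, in
    which case it is unphysical and p1 is the attractor.  With beta = 0
    the quadratic degenerates; p2 is returned as ``nan``.
    """
    p1 = 1.0 - params.sigma_I
    if params.beta == 0.0:
        return p1, math.nan
    return p1, (params.alpha / params.beta) * params.sigma_I


def critical_threshold(params: ModelParameters) -> float:
    """Critical inflexible fraction I_c = beta/(alpha + beta).

    At or above I_c the opponent-free equilibrium is the attractor.
    With alpha = 0 every sub-unit core fraction fails (I_c = 1); with
    beta = 0 any core at all suffices (I_c = 0).
    """
    denom = params.alpha + params.beta
    if denom == 0.0:
        raise ValueError("I_c undefined for alpha = beta = 0 (frozen dynamics)")
    return params.beta / denom


def min_core_engagement(sigma_I: float, beta: float) -> float:
    """Minimum conversion rate alpha* = (1/sigma_I - 1)*beta thwarting radicalization.

    Any alpha >= alpha* drives the opponent density to zero at equilibrium
    (the boundary itself is the marginal, power-law-approach case).
    """
    sigma_I = _require_finite("sigma_I", sigma_I)
    beta = _require_finite("beta", beta)
    if not 0.0 < sigma_I <= 1.0:
        raise ValueError(f"sigma_I must lie in (0, 1], got {sigma_I}")
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return (1.0 / sigma_I - 1.0) * beta


def stability(params: ModelParameters, *, tol: float = TOL) -> EquilibriumReport:
    """Linear stability of both fixed points and the selected equilibrium.

    The linearization eigenvalues are ``lambda1 = beta*(p1 - p2)`` at p1
    and ``lambda2 = -lambda1`` at p2; the root with negative eigenvalue
    (i.e. the smaller root) is stable.  Equality within *tol* is the
    marginal case: a single double root, approached as a power law, with
    the opponent-free equilibrium reached in the limit.
    """
    p1, p2 = equilibrium_roots(params)
    sigma_I = params.sigma_I
    regime = _case_label(sigma_I)

    if params.beta == 0.0:
        # Pure decay of sigma_O at rate alpha*sigma_I; only p1 remains.
        try:
            I_c = critical_threshold(params)
        except ValueError:
            I_c = math.nan
        return EquilibriumReport(
            p1=p1,
            p2=math.nan,
            lambda1=-params.alpha * sigma_I,
            lambda2=math.nan,
            stable_root="p1",
            sigma_P_eq=p1,
            sigma_O_eq=0.0,
            I_c=I_c,
            regime=regime,
            thwarted=True,
            degenerate_beta0=True,
        )

    lambda1 = params.beta * (p1 - p2)
    lambda2 = -lambda1
    I_c = critical_threshold(params)

    if abs(p1 - p2) <= tol:
        stable_root = "marginal"
        marginal = True
        thwarted = True  # sigma_O -> 0 algebraically, power-law approach
        sigma_P_eq, sigma_O_eq = p1, 0.0
    elif p1 < p2:
        stable_root = "p1"
        marginal = False
        thwarted = True
        sigma_P_eq, sigma_O_eq = p1, 0.0
    else:
        stable_root = "p2"
        marginal = False
        thwarted = False
        sigma_P_eq = p2
        sigma_O_eq = 1.0 - ((params.alpha + params.beta) / params.beta) * sigma_I

    return EquilibriumReport(
        p1=p1,
        p2=p2,
        lambda1=lambda1,
        lambda2=lambda2,
        stable_root=stable_root,
        sigma_P_eq=sigma_P_eq,
        sigma_O_eq=sigma_O_eq,
        I_c=I_c,
        regime=regime,
        thwarted=thwarted,
        marginal=marginal,
    )


def _case_label(sigma_I: float) -> str:
    if sigma_I > 0.5:
        return "case1"
    if sigma_I == 0.5:
        return "case2"
    return "case3"


def classify_regime(params: ModelParameters, *, tol: float = TOL) -> tuple[str, bool]:
    """Case label by core majority status, plus the thwarted flag.

    The label records whether the core is a majority (case1), exactly
    half (case2) or a minority (case3); the flag records whether the
    opponent-free equilibrium is selected (sigma_I >= I_c).  They are
    independent: a core majority can still fail to thwart when beta
    greatly exceeds alpha, and a small core can thwart with alpha large.
    """
    report = stability(params, tol=tol)
    return report.regime, report.thwarted
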