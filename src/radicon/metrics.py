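"""Degree-of-radicalization indices.

Two complementary scalars summarize how radicalized a population is:

* ``zeta = sigma_O / (1 - sigma_I)`` — opponents as a share of the
  flexible subpopulation, bounded in [0, 1].  zeta = 0 means no opponents;
  zeta = 1 means every flexible agent is an opponent.
* ``eta = sigma_O / sigma_I`` — opponents per inflexible agent, in
  [0, inf).  eta > 1 means opponents outnumber the core, regardless of
  how small zeta is — the "real power" of the opponents.

Both recover sigma_O: eta*sigma_I = zeta*(1 - sigma_I) = sigma_O.

The qualitative labels attached by :func:`interpret` are advisory
summaries with configurable cutoffs; they never feed back into any
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .trajectory import Trajectory

__all__ = [
    "RadicalizationMetrics",
    "radicalization_degree",
    "metrics_series",
    "interpret",
]


@dataclass(frozen=True)
class RadicalizationMetrics:
    """zeta and eta at one population state.

    ``eta_infinite`` flags the sigma_I = 0 limit, where eta is unbounded
    (eta is then ``math.inf``, not an error).
    """

    zeta: float
    eta: float
    eta_infinite: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError(f"zeta must lie in [0, 1], got {self.zeta}")
        if self.eta < 0.0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")


def radicalization_degree(sigma_I: float, sigma_O: float) -> RadicalizationMetrics:
    """Compute (zeta, eta) from the inflexible and opponent fractions.

    Edge cases: with sigma_I = 1 (no flexible agents) zeta is defined as
    0; with sigma_I = 0 eta is reported as flagged infinity (0 if there
    are also no opponents).
    """
    sigma_I = float(sigma_I)
    sigma_O = float(sigma_O)
    if not 0.0 <= sigma_I <= 1.0:
        raise ValueError(f"sigma_I must lie in [0, 1], got {sigma_I}")
    if sigma_O < 0.0 or sigma_I + sigma_O > 1.0 + 1e-9:
        raise ValueError(
            f"need sigma_O >= 0 and sigma_I + sigma_O <= 1, got "
            f"sigma_I={sigma_I}, sigma_O={sigma_O}"
        )

    flexible = 1.0 - sigma_I
    zeta = 0.0 if flexible == 0.0 else min(sigma_O / flexible, 1.0)

    if sigma_I == 0.0:
        if sigma_O == 0.0:
            return RadicalizationMetrics(zeta=zeta, eta=0.0)
        return RadicalizationMetrics(zeta=zeta, eta=math.inf, eta_infinite=True)
    return RadicalizationMetrics(zeta=zeta, eta=sigma_O / sigma_I)


def metrics_series(traj: "Trajectory") -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (zeta, eta) arrays over a trajectory's time grid."""
    sigma_I = traj.sigma_I
    sigma_O = np.asarray(traj.sigma_O, dtype=float)
    flexible = 1.0 - sigma_I
    if flexible == 0.0:
        zeta = np.zeros_like(sigma_O)
    else:
        zeta = np.minimum(sigma_O / flexible, 1.0)
    if sigma_I == 0.0:
        eta = np.where(sigma_O == 0.0, 0.0, np.inf)
    else:
        eta = sigma_O / sigma_I
    return zeta, eta


def interpret(
    metrics: RadicalizationMetrics,
    sigma_I: float,
    *,
    zeta_low: float = 0.25,
    zeta_high: float = 0.75,
    eta_high: float = 1.0,
) -> str:
    """Qualitative label for a (zeta, eta) pair given the core fraction.

    Returns one of ``contained``, ``latent-warning``, ``alarming``,
    ``fully-radicalized``:

    * few opponents in both senses -> ``contained``;
    * few opponents among the flexible but more opponents than
      inflexibles (eta > eta_high) -> ``alarming``: the opponents'
      absolute power exceeds the core's;
    * most flexible agents radicalized (zeta > zeta_high) in a
      core-majority population -> ``latent-warning``: counter-strategies
      are failing but opponents are few in absolute terms;
    * most flexible agents radicalized otherwise -> ``fully-radicalized``.

    The cutoffs are illustrative defaults, not part of the model.
    """
    if metrics.zeta > zeta_high:
        return "latent-warning" if sigma_I > 0.5 else "fully-radicalized"
    if metrics.eta > eta_high:
        return "alarming"
    return "contained"
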