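"""Finite-population stochastic counterpart of the mean-field model.

The microdynamics is a well-mixed continuous-time Markov chain over two
aggregate reaction channels,

* conversion O -> P at total rate ``alpha * (n_I / N) * n_O``
  (each opponent meets inflexibles in proportion to their density), and
* conversion P -> O at total rate ``beta * (n_O / N) * n_P``,

simulated exactly with the Gillespie direct method.  With these per-capita
hazards the expected densities obey the mean-field ODE with the *same*
alpha and beta: E[d sigma_O/dt] = beta*sigma_O*sigma_P - alpha*sigma_I*sigma_O
up to O(1/N) fluctuations, so finite-N runs converge on the ODE
equilibrium as N grows.

The chain absorbs when the active channel rates vanish: at n_O = 0
(opponents extinct — possible whenever sigma_I >= I_c drives the mean
field there, and always possible at finite N by fluctuation), or at
n_P = 0 with alpha*n_I = 0 (no inflow back to peaceful).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParameters

__all__ = ["ABMConfig", "ReplicateResult", "ABMResult", "run_abm", "summarize_replicates"]

_BATCH = 4096  # random numbers drawn per RNG call inside the event loop


@dataclass(frozen=True)
class ABMConfig:
    """Settings for one batch of stochastic realizations.

    ``seed`` is mandatory for reproducibility: identical (config, seed)
    yields bit-identical event series.  Replicate r uses the child stream
    ``SeedSequence(seed).spawn(replicates)[r]``.
    """

    N: int
    n_I: int
    n_P: int
    n_O: int
    alpha: float
    beta: float
    t_max: float
    seed: int
    replicates: int = 1
    record_series: bool = True

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be a positive integer")
        if min(self.n_I, self.n_P, self.n_O) < 0:
            raise ValueError("initial counts must be >= 0")
        if self.n_I + self.n_P + self.n_O != self.N:
            raise ValueError(
                f"counts must sum to N: {self.n_I}+{self.n_P}+{self.n_O} != {self.N}"
            )
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_densities(
        cls,
        params: ModelParameters,
        N: int,
        sigma_O0: float,
        t_max: float,
        seed: int,
        replicates: int = 1,
        record_series: bool = True,
    ) -> "ABMConfig":
        """Build a config by rounding target densities to integer counts."""
        n_I = round(params.sigma_I * N)
        n_O = round(sigma_O0 * N)
        n_P = N - n_I - n_O
        if n_P < 0:
            raise ValueError("sigma_I + sigma_O0 exceeds 1 at this N")
        return cls(
            N=N,
            n_I=n_I,
            n_P=n_P,
            n_O=n_O,
            alpha=params.alpha,
            beta=params.beta,
            t_max=t_max,
            seed=seed,
            replicates=replicates,
            record_series=record_series,
        )


@dataclass(frozen=True)
class ReplicateResult:
    """One realization: event series (optional) and final state."""

    replicate: int
    t: np.ndarray  # event times, t[0] = 0
    n_P: np.ndarray
    n_O: np.ndarray
    final_t: float
    final_n_P: int
    final_n_O: int
    absorbed: bool
    n_events: int


@dataclass(frozen=True)
class ABMResult:
    """All replicates of one config, plus the config itself (seed included)."""

    config: ABMConfig
    replicates: list[ReplicateResult] = field(repr=False)

    def final_densities(self) -> tuple[np.ndarray, np.ndarray]:
        """(sigma_P, sigma_O) arrays of per-replicate final states."""
        N = self.config.N
        sP = np.array([r.final_n_P for r in self.replicates], dtype=float) / N
        sO = np.array([r.final_n_O for r in self.replicates], dtype=float) / N
        return sP, sO


def _run_one(
    config: ABMConfig, rng: np.random.Generator, replicate: int
) -> ReplicateResult:
    # Gillespie direct method over the two aggregate channels.
    N = config.N
    n_I = config.n_I
    n_P = config.n_P
    n_O = config.n_O
    a_frac = config.alpha * n_I / N  # per-opponent O->P hazard
    b_over_N = config.beta / N
    t = 0.0
    t_max = config.t_max
    record = config.record_series

    times = [0.0]
    series_P = [n_P]
    series_O = [n_O]
    n_events = 0
    absorbed = False

    # draw randoms in batches: one exponential (waiting time) and one
    # uniform (channel choice) per event
    exp_batch = rng.exponential(size=_BATCH)
    uni_batch = rng.random(size=_BATCH)
    idx = 0

    while True:
        r1 = a_frac * n_O          # O -> P
        r2 = b_over_N * n_O * n_P  # P -> O
        total = r1 + r2
        if total == 0.0:
            absorbed = True
            break
        if idx == _BATCH:
            exp_batch = rng.exponential(size=_BATCH)
            uni_batch = rng.random(size=_BATCH)
            idx = 0
        t_next = t + exp_batch[idx] / total
        if t_next > t_max:
            break
        t = t_next
        if uni_batch[idx] * total < r1:
            n_O -= 1
            n_P += 1
        else:
            n_P -= 1
            n_O += 1
        idx += 1
        n_events += 1
        if record:
            times.append(t)
            series_P.append(n_P)
            series_O.append(n_O)

    if not record:
        times = [0.0, t] if n_events else [0.0]
        series_P = [config.n_P, n_P] if n_events else [config.n_P]
        series_O = [config.n_O, n_O] if n_events else [config.n_O]

    return ReplicateResult(
        replicate=replicate,
        t=np.asarray(times),
        n_P=np.asarray(series_P),
        n_O=np.asarray(series_O),
        final_t=t,
        final_n_P=n_P,
        final_n_O=n_O,
        absorbed=absorbed,
        n_events=n_events,
    )


def run_abm(config: ABMConfig) -> ABMResult:
    """Run all replicates of the exact stochastic simulation.

    Warns (via ``RuntimeWarning``) when both channel rates start at zero,
    i.e. the system is frozen from the outset.
    """
    r1 = config.alpha * config.n_I * config.n_O
    r2 = config.beta * config.n_O * config.n_P
    if r1 == 0 and r2 == 0:
        import warnings

        warnings.warn(
            "both reaction rates are zero at t=0: the system is frozen",
            RuntimeWarning,
            stacklevel=2,
        )
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    results = [
        _run_one(config, np.random.default_rng(child), r)
        for r, child in enumerate(children)
    ]
    return ABMResult(config=config, replicates=results)


def summarize_replicates(result: ABMResult) -> dict:
    """Cross-replicate summary of final states.

    Densities are counts/N.  The standard error is ``nan`` (flagged) for
    a single replicate.
    """
    sP, sO = result.final_densities()
    n = len(sP)
    se = float("nan") if n < 2 else float(np.std(sO, ddof=1) / math.sqrt(n))
    se_P = float("nan") if n < 2 else float(np.std(sP, ddof=1) / math.sqrt(n))
    return {
        "n_replicates": n,
        "seed": result.config.seed,
        "mean_sigma_P": float(np.mean(sP)),
        "mean_sigma_O": float(np.mean(sO)),
        "se_sigma_P": se_P,
        "se_sigma_O": se,
        "min_sigma_O": float(np.min(sO)),
        "max_sigma_O": float(np.max(sO)),
        "min_sigma_P": float(np.min(sP)),
        "max_sigma_P": float(np.max(sP)),
        "fraction_absorbed": float(
            np.mean([r.absorbed for r in result.replicates])
        ),
    }
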