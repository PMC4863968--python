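"""Scenario configuration, worked-example fixtures, and serialization.

A scenario is fully specified by the 4-tuple (sigma_I, sigma_O0, alpha,
beta) — the initial condition is given as the opponent fraction
sigma_O(0), with sigma_P(0) = 1 - sigma_I - sigma_O(0) implied — plus
integration and stochastic-simulation settings.  Configs round-trip
losslessly through flat-key YAML, and every run can emit a provenance
block (tool version, config hash, seed).

``fig1_fixtures`` returns the nine canonical demonstration scenarios
(keyed "a" through "i") spanning all three regimes: coexistence,
opponent extinction, and the near-fully-radicalized start.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model_core import ModelParameters, PopulationState

__all__ = ["ScenarioConfig", "fig1_fixtures", "provenance_block"]


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully-specified scenario: model, initial condition, run settings."""

    sigma_I: float
    sigma_O0: float
    alpha: float
    beta: float
    t_max: float | None = None     # None -> relaxation-scaled default
    n_points: int = 512
    n_agents: int = 10_000          # stochastic runs only
    replicates: int = 1
    seed: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        # delegate parameter validation; also checks the initial condition
        p = self.params
        if self.sigma_O0 < 0 or self.sigma_O0 > p.sigma_S + 1e-12:
            raise ValueError(
                f"sigma_O0={self.sigma_O0} outside [0, 1 - sigma_I = {p.sigma_S}]"
            )

    @property
    def params(self) -> ModelParameters:
        return ModelParameters(sigma_I=self.sigma_I, alpha=self.alpha, beta=self.beta)

    @property
    def sigma_P0(self) -> float:
        return 1.0 - self.sigma_I - self.sigma_O0

    def initial_state(self) -> PopulationState:
        return PopulationState(t=0.0, sigma_P=self.sigma_P0, sigma_O=self.sigma_O0)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        """Flat-key YAML mirroring the CLI flags; lossless round-trip."""
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScenarioConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat key: value mapping")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def provenance_block(config: ScenarioConfig) -> dict:
    """Provenance metadata attached to every serialized run."""
    from . import __version__

    return {
        "tool": "radicon",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


#: The nine worked demonstration scenarios, (sigma_I, sigma_O0, alpha, beta).
_FIG1 = {
    "a": (0.30, 0.30, 1.0, 1.0),
    "b": (0.30, 0.30, 1.0, 2.0),
    "c": (0.30, 0.30, 4.0, 2.0),
    "d": (0.28, 0.02, 0.5, 0.5),
    "e": (0.30, 0.30, 1.0, 5.0),
    "f": (0.10, 0.40, 4.0, 2.0),
    "g": (0.10, 0.40, 12.0, 2.0),
    "h": (0.10, 0.40, 22.0, 2.0),
    "i": (0.28, 0.70, 0.5, 0.5),
}


def fig1_fixtures() -> dict[str, ScenarioConfig]:
    """The nine canonical scenarios, keyed "a" through "i"."""
    return {
        key: ScenarioConfig(
            sigma_I=sI, sigma_O0=sO0, alpha=alpha, beta=beta, name=key
        )
        for key, (sI, sO0, alpha, beta) in _FIG1.items()
    }
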