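"""Regime maps over parameter space.

The thwarted/permanent boundary depends on (sigma_I, alpha, beta) only
through the ratio alpha/beta: radicalization is thwarted exactly when
``alpha/beta >= 1/sigma_I - 1``, the hyperbola separating the two regions
of the phase plane.  This module classifies rectangular grids over
(sigma_I, alpha/beta), attaches equilibrium densities and radicalization
indices per cell, and optionally renders the two-region map.  The tabular
grid is the tested artifact; the figure is cosmetic.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .metrics import radicalization_degree
from .model_core import TOL, ModelParameters, stability

__all__ = ["classify_grid", "equilibrium_surface", "plot_phase_diagram"]

GRID_COLUMNS = ["sigma_I", "ratio", "thwarted", "marginal", "sigma_O_eq", "zeta_eq", "eta_eq"]


def default_sigma_I_grid(n: int = 99) -> np.ndarray:
    """n evenly spaced core fractions on [0.01, 0.99]."""
    return np.linspace(0.01, 0.99, n)


def default_ratio_grid(n: int = 100) -> np.ndarray:
    """n log-spaced alpha/beta ratios on [0.01, 100], resolving the hyperbola."""
    return np.logspace(-2, 2, n)


def _cell(sigma_I: float, ratio: float, tol: float) -> dict:
    # beta = 1 without loss of generality: the classification and the
    # equilibrium densities depend only on alpha/beta
    params = ModelParameters(sigma_I=sigma_I, alpha=ratio, beta=1.0)
    rep = stability(params, tol=tol)
    m = radicalization_degree(sigma_I, max(rep.sigma_O_eq, 0.0))
    return {
        "sigma_I": sigma_I,
        "ratio": ratio,
        "thwarted": rep.thwarted,
        "marginal": rep.marginal,
        "sigma_O_eq": rep.sigma_O_eq,
        "zeta_eq": m.zeta,
        "eta_eq": m.eta,
    }


def classify_grid(
    sigma_I_values: Sequence[float] | np.ndarray | None = None,
    ratio_values: Sequence[float] | np.ndarray | None = None,
    *,
    tol: float = TOL,
) -> pd.DataFrame:
    """Classify every (sigma_I, alpha/beta) cell of a rectangular grid.

    Each row carries the thwarted flag (``ratio >= 1/sigma_I - 1``,
    boundary inclusive and additionally flagged ``marginal``), the
    equilibrium opponent density and the equilibrium indices zeta, eta.

    Raises
    ------
    ValueError
        If any sigma_I lies outside the open interval (0, 1), or a grid
        is empty.
    """
    sig = np.asarray(
        default_sigma_I_grid() if sigma_I_values is None else sigma_I_values,
        dtype=float,
    )
    rat = np.asarray(
        default_ratio_grid() if ratio_values is None else ratio_values, dtype=float
    )
    if sig.size == 0 or rat.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any((sig <= 0.0) | (sig >= 1.0)):
        raise ValueError("sigma_I grid values must lie strictly inside (0, 1)")
    if np.any(rat < 0.0):
        raise ValueError("ratio grid values must be >= 0")

    rows = [_cell(s, r, tol) for s in sig for r in rat]
    df = pd.DataFrame(rows, columns=GRID_COLUMNS)
    df["curve"] = 1.0 / df["sigma_I"] - 1.0  # the boundary hyperbola per row
    return df


def equilibrium_surface(params_grid: Sequence[ModelParameters]) -> pd.DataFrame:
    """Equilibrium densities and indices for an arbitrary parameter list.

    Unlike :func:`classify_grid` this takes full (sigma_I, alpha, beta)
    parameter sets (beta > 0 required).  The opponent surface is
    continuous across the critical boundary: both branches give
    sigma_O_eq = 0 there.
    """
    rows = []
    for p in params_grid:
        if p.beta <= 0.0:
            raise ValueError("equilibrium_surface requires beta > 0 on all cells")
        rep = stability(p)
        m = radicalization_degree(p.sigma_I, max(rep.sigma_O_eq, 0.0))
        rows.append(
            {
                "sigma_I": p.sigma_I,
                "alpha": p.alpha,
                "beta": p.beta,
                "sigma_P_eq": rep.sigma_P_eq,
                "sigma_O_eq": rep.sigma_O_eq,
                "zeta_eq": m.zeta,
                "eta_eq": m.eta,
            }
        )
    return pd.DataFrame(rows)


def plot_phase_diagram(grid: pd.DataFrame, path: str | None = None):
    """Render the two-region thwarted/permanent map with the boundary curve.

    Cosmetic companion to :func:`classify_grid`; returns the Matplotlib
    figure, saving it to *path* when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    thwarted = grid[grid["thwarted"]]
    permanent = grid[~grid["thwarted"]]
    ax.scatter(thwarted["sigma_I"], thwarted["ratio"], s=4, c="gold",
               label="thwarted (sigma_O_eq = 0)")
    ax.scatter(permanent["sigma_I"], permanent["ratio"], s=4, c="navy",
               label="permanent radicalization")
    s = np.linspace(grid["sigma_I"].min(), grid["sigma_I"].max(), 400)
    ax.plot(s, 1.0 / s - 1.0, "k-", lw=1.5, label=r"$\alpha/\beta = 1/\sigma_I - 1$")
    ax.set_yscale("log")
    ax.set_xlabel(r"inflexible fraction $\sigma_I$")
    ax.set_ylabel(r"engagement ratio $\alpha/\beta$")
    ax.set_ylim(grid["ratio"].min(), grid["ratio"].max())
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
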