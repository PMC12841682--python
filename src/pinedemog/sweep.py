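"""One-at-a-time perturbation sweeps of survivals and fecundity.

Each sweep replaces a single matrix entry with each value of a grid, holds
everything else at baseline, recomputes λ, and records the smallest grid
value at which λ strictly exceeds 1 (the replacement threshold). Because
λ = (F·∏g)^(1/6) on a single loop, λ is strictly increasing along every
grid, so the threshold — when the grid reaches it — is unique.

Default grids follow the published design: survivals 0.1–1.0 in steps of
0.1 (absolute probabilities, not multipliers), fecundity 50–500 in steps
of 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .projection import (
    FECUNDITY_PARAM,
    PARAMETERS,
    TRANSITIONS,
    ProjectionModel,
    growth_rate,
)

#: Survival grid: 0.1, 0.2, …, 1.0 (inclusive endpoints).
SURVIVAL_GRID: np.ndarray = np.linspace(0.1, 1.0, 10)

#: Fecundity grid: 50, 60, …, 500 eggs per 1000 cm².
FECUNDITY_GRID: np.ndarray = np.arange(50.0, 501.0, 10.0)


@dataclass(frozen=True)
class SweepResult:
    """λ along one parameter grid, with the λ > 1 crossing if reached."""

    parameter: str
    grid: np.ndarray
    lambdas: np.ndarray
    threshold: float | None
    baseline_value: float
    baseline_lambda: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "grid_value": self.grid,
                "lambda": self.lambdas,
            }
        )


def _sweep(model: ProjectionModel, parameter: str, grid: np.ndarray) -> SweepResult:
    if grid.size == 0:
        raise ValueError("sweep grid must be non-empty")
    lambdas = np.array(
        [growth_rate(model.with_entry(parameter, float(v))) for v in grid]
    )
    above = np.nonzero(lambdas > 1.0)[0]
    threshold = float(grid[above[0]]) if above.size else None
    i, j = model.entry_index(parameter)
    return SweepResult(
        parameter=parameter,
        grid=np.asarray(grid, dtype=float),
        lambdas=lambdas,
        threshold=threshold,
        baseline_value=float(model.A[i, j]),
        baseline_lambda=growth_rate(model),
    )


def sweep_survival(
    model: ProjectionModel,
    transition: str,
    grid: Sequence[float] | np.ndarray = SURVIVAL_GRID,
) -> SweepResult:
    """Sweep one survival transition over a grid of absolute probabilities."""
    if transition not in TRANSITIONS:
        raise ValueError(
            f"unknown transition {transition!r}; valid transitions: {TRANSITIONS}"
        )
    return _sweep(model, transition, np.asarray(grid, dtype=float))


def sweep_fecundity(
    model: ProjectionModel, grid: Sequence[float] | np.ndarray = FECUNDITY_GRID
) -> SweepResult:
    """Sweep the fecundity corner entry, survivals held at baseline."""
    return _sweep(model, FECUNDITY_PARAM, np.asarray(grid, dtype=float))


def sweep_all(model: ProjectionModel) -> list[SweepResult]:
    """All six default sweeps: five survivals then fecundity."""
    results = [sweep_survival(model, t) for t in TRANSITIONS]
    results.append(sweep_fecundity(model))
    return results


def crossing_report(results: Iterable[SweepResult]) -> pd.DataFrame:
    """One row per swept parameter: baseline value, baseline λ, threshold.

    The threshold column holds the smallest grid value with λ > 1, or the
    string ``"none"`` when the grid never crosses.
    """
    rows = [
        {
            "parameter": r.parameter,
            "baseline_value": r.baseline_value,
            "baseline_lambda": r.baseline_lambda,
            "threshold": r.threshold if r.threshold is not None else "none",
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["parameter", "baseline_value", "baseline_lambda", "threshold"]
    )


def plot_sweeps(results: Sequence[SweepResult], path: str | None = None):
    """Sweep curves (λ vs parameter value), survival and fecundity panels.

    Returns the matplotlib figure; saves to ``path`` (SVG/PNG by extension)
    when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surv = [r for r in results if r.parameter != FECUNDITY_PARAM]
    fec = [r for r in results if r.parameter == FECUNDITY_PARAM]
    ncols = (1 if surv else 0) + (1 if fec else 0)
    fig, axes = plt.subplots(1, max(ncols, 1), figsize=(5 * max(ncols, 1), 4))
    axes = np.atleast_1d(axes)
    col = 0
    if surv:
        ax = axes[col]
        for r in surv:
            ax.plot(r.grid, r.lambdas, marker="o", ms=3, label=r.parameter)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("survival probability")
        ax.set_ylabel("population growth rate λ")
        ax.legend(fontsize=8)
        col += 1
    if fec:
        ax = axes[col]
        for r in fec:
            ax.plot(r.grid, r.lambdas, marker="o", ms=3, color="C3")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("fecundity (eggs per 1000 cm²)")
        ax.set_ylabel("population growth rate λ")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


__all__ = [
    "SURVIVAL_GRID",
    "FECUNDITY_GRID",
    "SweepResult",
    "sweep_survival",
    "sweep_fecundity",
    "sweep_all",
    "crossing_report",
    "plot_sweeps",
    "PARAMETERS",
]
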