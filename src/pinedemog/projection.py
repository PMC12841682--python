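"""Single-loop stage projection matrix and its eigen-analysis.

The univoltine life cycle E → L1 → L2 → L3 → L4 → P → (adults) → E maps to
a 6×6 non-negative matrix with the five stage-to-stage survivals on the
subdiagonal and realized fecundity F in the top-right corner (adult
survival and oviposition are collapsed into that corner entry). The
directed graph of nonzero entries is a single 6-cycle, so the matrix is
irreducible but imprimitive with index 6: all six eigenvalues share the
modulus (F·∏g)^(1/6). Power iteration therefore never converges; the
Perron root is taken from a dense eigendecomposition as the unique
eigenvalue that is real and positive.

Sensitivities follow the classical formula s_ij = v_i·w_j / ⟨v, w⟩ with w
the stable stage distribution (right eigenvector, normalised to sum 1) and
v the reproductive-value vector (left eigenvector, first entry 1);
elasticities are e_ij = (a_ij/λ)·s_ij. On a single loop every structural
elasticity equals 1/6 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lifetable import STAGES, LifeTable

#: Names of the five survival transitions, in loop order.
TRANSITIONS: tuple[str, ...] = ("E->L1", "L1->L2", "L2->L3", "L3->L4", "L4->P")

#: The fecundity parameter identifier (top-right corner entry).
FECUNDITY_PARAM: str = "F"

#: All six sweep-able parameters.
PARAMETERS: tuple[str, ...] = TRANSITIONS + (FECUNDITY_PARAM,)

_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class ProjectionModel:
    """A 6×6 single-loop projection matrix with stage labels."""

    stage_labels: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        k = len(self.stage_labels)
        if A.shape != (k, k):
            raise ValueError(f"matrix shape {A.shape} does not match {k} stages")
        if np.any(A < 0):
            raise ValueError("projection matrix entries must be non-negative")
        expected = {(i + 1, i) for i in range(k - 1)} | {(0, k - 1)}
        nonzero = set(zip(*np.nonzero(A)))
        if nonzero != expected:
            raise ValueError(
                "matrix is not a single loop: nonzero entries must be the "
                "subdiagonal plus the top-right corner"
            )
        object.__setattr__(self, "A", A)

    @property
    def survivals(self) -> np.ndarray:
        """The five subdiagonal survival entries, in loop order."""
        return np.diagonal(self.A, offset=-1).copy()

    @property
    def fecundity(self) -> float:
        return float(self.A[0, -1])

    def entry_index(self, parameter: str) -> tuple[int, int]:
        """Matrix position of a named parameter (transition or ``"F"``)."""
        if parameter == FECUNDITY_PARAM:
            return (0, len(self.stage_labels) - 1)
        if parameter in TRANSITIONS:
            i = TRANSITIONS.index(parameter)
            return (i + 1, i)
        raise ValueError(
            f"unknown parameter {parameter!r}; valid parameters: {PARAMETERS}"
        )

    def with_entry(self, parameter: str, value: float) -> "ProjectionModel":
        """A copy of the model with one named entry replaced."""
        if value < 0:
            raise ValueError("matrix entries must be non-negative")
        i, j = self.entry_index(parameter)
        A = self.A.copy()
        A[i, j] = value
        return ProjectionModel(self.stage_labels, A)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.A, index=self.stage_labels, columns=self.stage_labels).to_csv(
            path
        )


def build_matrix(life_table: LifeTable) -> ProjectionModel:
    """Assemble the single-loop matrix from a 6-stage life table."""
    if len(life_table.stages) != 6:
        raise ValueError(
            f"projection model requires 6 stages, life table has "
            f"{len(life_table.stages)}"
        )
    g = life_table.g_x[1:]
    undefined = [
        life_table.stages[i + 1] for i, gi in enumerate(g) if not np.isfinite(gi)
    ]
    if undefined:
        raise ValueError(
            f"survival undefined for stage(s): {', '.join(undefined)}"
        )
    if not life_table.fecundity > 0:
        raise ValueError("fecundity must be positive")
    A = np.zeros((6, 6))
    A[np.arange(1, 6), np.arange(5)] = g
    A[0, 5] = life_table.fecundity
    return ProjectionModel(tuple(life_table.stages), A)


def _dominant_eigenpair(A: np.ndarray) -> tuple[float, np.ndarray]:
    """The positive real eigenvalue and its right eigenvector.

    All eigenvalues of a single-loop matrix share the same modulus, so the
    Perron root is identified by realness and sign, not magnitude.
    """
    values, vectors = np.linalg.eig(A)
    scale = max(1.0, float(np.max(np.abs(values))))
    real = np.abs(values.imag) <= _IMAG_TOL * scale
    positive = values.real > 0
    candidates = np.nonzero(real & positive)[0]
    if len(candidates) == 0:
        raise ValueError("no positive real eigenvalue found")
    idx = candidates[np.argmax(values.real[candidates])]
    vec = vectors[:, idx].real
    if vec.sum() < 0:
        vec = -vec
    return float(values[idx].real), vec


def growth_rate(model: ProjectionModel) -> float:
    """Asymptotic per-step growth rate λ (the Perron root)."""
    lam, _ = _dominant_eigenpair(model.A)
    return lam


def stable_structure(model: ProjectionModel) -> np.ndarray:
    """Stable stage distribution w: right eigenvector of λ, summing to 1."""
    _, w = _dominant_eigenpair(model.A)
    w = np.abs(w)
    return w / w.sum()


def reproductive_value(model: ProjectionModel) -> np.ndarray:
    """Reproductive values v: left eigenvector of λ, first entry 1."""
    _, v = _dominant_eigenpair(model.A.T)
    return v / v[0]


def sensitivity_matrix(model: ProjectionModel) -> np.ndarray:
    """Full sensitivity matrix S = v wᵀ / ⟨v, w⟩ (∂λ/∂a_ij)."""
    w = stable_structure(model)
    v = reproductive_value(model)
    return np.outer(v, w) / float(v @ w)


def elasticity_matrix(model: ProjectionModel) -> np.ndarray:
    """Elasticities E = (A/λ) ∘ S; zero wherever A is zero, summing to 1."""
    lam = growth_rate(model)
    return model.A / lam * sensitivity_matrix(model)


@dataclass(frozen=True)
class EigenAnalysis:
    """λ, stable structure, reproductive values, sensitivities, elasticities.

    ``lambda_`` is the per-projection-step growth rate; because the six
    stage transitions together span one year, ``lambda_annual = lambda_**6``
    is the per-year (per-generation) rate.
    """

    lambda_: float
    lambda_annual: float
    w: np.ndarray
    v: np.ndarray
    S: np.ndarray
    E6: np.ndarray

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_,
            "lambda_annual": self.lambda_annual,
            "stable_structure": self.w.tolist(),
            "reproductive_value": self.v.tolist(),
            "sensitivities": self.S.tolist(),
            "elasticities": self.E6.tolist(),
        }


def eigen_analysis(model: ProjectionModel, rtol: float = 1e-9) -> EigenAnalysis:
    """Full eigen-analysis of the model, with eigen-equation residual checks."""
    lam = growth_rate(model)
    w = stable_structure(model)
    v = reproductive_value(model)
    scale = lam * max(1.0, float(np.abs(w).max()))
    if not np.allclose(model.A @ w, lam * w, rtol=0, atol=rtol * scale):
        raise ArithmeticError("right eigen-equation residual exceeds tolerance")
    vscale = lam * float(np.abs(v).max())
    if not np.allclose(v @ model.A, lam * v, rtol=0, atol=rtol * vscale):
        raise ArithmeticError("left eigen-equation residual exceeds tolerance")
    S = np.outer(v, w) / float(v @ w)
    return EigenAnalysis(
        lambda_=lam,
        lambda_annual=lam**6,
        w=w,
        v=v,
        S=S,
        E6=model.A / lam * S,
    )


def structural_sensitivities(model: ProjectionModel) -> Mapping[str, float]:
    """Sensitivities of the six structural (nonzero) entries, by parameter.

    Keys are the transition names plus ``"F"``. For per-stage bar reports
    each survival transition is conventionally labelled by its destination
    stage (E->L1 as "L1", …) and fecundity by "E".
    """
    S = sensitivity_matrix(model)
    return {p: float(S[model.entry_index(p)]) for p in PARAMETERS}


#: Destination-stage labels for bar-style reporting of structural entries.
STRUCTURAL_LABELS: Mapping[str, str] = {
    "F": "E",
    "E->L1": "L1",
    "L1->L2": "L2",
    "L2->L3": "L3",
    "L3->L4": "L4",
    "L4->P": "P",
}


def default_model() -> ProjectionModel:
    """The published matrix: printed survivals and egg density."""
    from .lifetable import printed_life_table

    return build_matrix(printed_life_table())


__all__ = [
    "STAGES",
    "TRANSITIONS",
    "FECUNDITY_PARAM",
    "PARAMETERS",
    "ProjectionModel",
    "EigenAnalysis",
    "build_matrix",
    "growth_rate",
    "stable_structure",
    "reproductive_value",
    "sensitivity_matrix",
    "elasticity_matrix",
    "eigen_analysis",
    "structural_sensitivities",
    "STRUCTURAL_LABELS",
    "default_model",
]
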