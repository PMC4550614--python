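"""Competitive-import equilibrium output model.

Solves the Leontief system with competitive imports,

    X = [I - (I - M) A]^-1 [(I - M) Y + E],

where ``A`` is the input-coefficient matrix, ``M = diag(m)`` the diagonal
matrix of import coefficients, ``Y`` domestic final demand and ``E``
exports.  Pre-multiplying by ``(I - M)`` confines the induced production to
domestic output: the imported share of every round of demand leaks out of
the economy.  A nonnegative solution exists iff the spectral radius of the
domestic coefficient matrix ``(I - M) A`` is below one (the Hawkins-Simon
viability condition); the solver checks this and solves the linear system
directly rather than materializing the inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "EquilibriumInputs",
    "InducedProduction",
    "ViabilityError",
    "domestic_induced_production",
    "viability_check",
    "leontief_inverse",
]

logger = logging.getLogger(__name__)

_NEGATIVE_CLAMP = 1e-9


class ViabilityError(ValueError):
    """The system has no nonnegative solution (spectral radius >= 1)."""


@dataclass
class EquilibriumInputs:
    """Inputs to the equilibrium output model.

    ``E`` defaults to the zero vector: the consumption route injects
    only domestic household demand.
    """

    A: np.ndarray
    m: np.ndarray
    Y: np.ndarray
    E: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.E is None:
            self.E = np.zeros(n)
        self.E = np.asarray(self.E, dtype=float)
        for name in ("m", "Y", "E"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.any(self.Y < 0) or np.any(self.E < 0):
            raise ValueError("Y and E must be nonnegative")
        if np.any((self.m < 0) | (self.m > 1)):
            raise ValueError("import coefficients must lie in [0, 1]")


@dataclass
class InducedProduction:
    """Per-sector domestic induced production and its total."""

    X: np.ndarray
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.total = float(self.X.sum())


def viability_check(A: np.ndarray, m: np.ndarray) -> tuple[float, bool]:
    """Spectral radius of ``(I - diag(m)) A`` and whether it is below 1."""
    A = np.asarray(A, dtype=float)
    m = np.asarray(m, dtype=float)
    if A.shape != (m.shape[0], m.shape[0]):
        raise ValueError("dimension mismatch between A and m")
    domestic = (1.0 - m)[:, np.newaxis] * A
    rho = float(np.max(np.abs(np.linalg.eigvals(domestic)))) if A.size else 0.0
    return rho, rho < 1.0


def domestic_induced_production(inputs: EquilibriumInputs) -> InducedProduction:
    """Solve ``[I - (I - M) A] X = (I - M) Y + E`` for X.

    Raises :class:`ViabilityError` when the spectral radius of the
    domestic coefficient matrix is >= 1.  Tiny negative round-off in X
    (above ``-1e-9``) is clamped to zero and logged; anything more
    negative indicates inconsistent inputs and raises.
    """
    rho, ok = viability_check(inputs.A, inputs.m)
    if not ok:
        raise ViabilityError(
            f"system not viable: spectral radius of (I - M)A is {rho:.6g} >= 1"
        )
    n = inputs.A.shape[0]
    keep = 1.0 - inputs.m
    lhs = np.eye(n) - keep[:, np.newaxis] * inputs.A
    rhs = keep * inputs.Y + inputs.E
    X = scipy.linalg.solve(lhs, rhs)
    neg = X < 0
    if np.any(X < -_NEGATIVE_CLAMP):
        raise ViabilityError(
            f"negative induced production (min {X.min():.3e}); inputs inconsistent"
        )
    if np.any(neg):
        logger.debug("clamping %d tiny negative entries to 0", int(neg.sum()))
        X = np.where(neg, 0.0, X)
    return InducedProduction(X=X)


def leontief_inverse(A: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Diagnostic: the matrix ``[I - (I - diag(m)) A]^-1`` itself.

    Exposed for inspection of sector-to-sector multipliers only; the
    solver never forms it.
    """
    rho, ok = viability_check(A, m)
    if not ok:
        raise ViabilityError(f"spectral radius {rho:.6g} >= 1")
    n = np.asarray(A).shape[0]
    keep = 1.0 - np.asarray(m, dtype=float)
    return np.linalg.inv(np.eye(n) - keep[:, np.newaxis] * np.asarray(A, dtype=float))
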