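"""Connectome containers: sparse structural and dense functional matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StructuralConnectome", "FunctionalConnectome", "check_symmetric"]

SYM_TOL = 1e-12


def check_symmetric(m: np.ndarray, tol: float = SYM_TOL, name: str = "matrix") -> None:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, rtol=0, equal_nan=True):
        raise ValueError(f"{name} is not symmetric within {tol}")


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative weighted adjacency with zero diagonal.

    The binary mask (weight > 0) defines the monosynaptic/polysynaptic
    partition of node pairs that the sgFC transform is built on.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        check_symmetric(w, name="structural weights")
        if np.any(w < 0):
            raise ValueError("structural weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("structural diagonal must be zero")
        # store exactly symmetric
        self.weights = (w + w.T) / 2.0

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def binary_mask(self) -> np.ndarray:
        return self.weights > 0

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> np.ndarray:
        """Upper-triangle edges as an (m, 2) index array, i < j."""
        i, j = np.where(np.triu(self.binary_mask, k=1))
        return np.column_stack([i, j])


@dataclass
class FunctionalConnectome:
    """Symmetric correlation-like matrix, values in [-1, 1], unit diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        check_symmetric(w, name="functional weights")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("functional weights must lie in [-1, 1]")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 1.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]
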