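"""Diffusion map embedding of functional connectivity.

Places regions on smooth macroscale gradients (the first component is
the putative unimodal–transmodal hierarchy).  Data points are the FC
row-profiles; a Gaussian affinity kernel over profile distances is
turned into an ergodic Markov operator via the alpha-normalized graph
Laplacian, and the operator's leading nontrivial eigenvectors are the
embedding coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .matrices import FunctionalConnectome

__all__ = [
    "GradientConfig",
    "GradientResult",
    "gaussian_affinity",
    "diffusion_embed",
    "embed_fc",
    "orient_gradient",
]


@dataclass(frozen=True)
class GradientConfig:
    """alpha: density-normalization exponent of the diffusion operator
    (1 = Laplace–Beltrami); sigma: Gaussian affinity width;
    n_components: number of nontrivial components kept.
    direct_affinity: treat the FC matrix itself (shifted to be
    nonnegative) as the affinity instead of Gaussian row-profile
    affinities."""

    alpha: float = 1.0
    sigma: float = 1.0
    n_components: int = 3
    direct_affinity: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class GradientResult:
    """Embedding components (nodes x k), eigenvalues (descending), and
    the reference used to fix component signs, if any."""

    components: np.ndarray
    eigenvalues: np.ndarray
    orientation_reference: np.ndarray | None = None


def gaussian_affinity(fc: FunctionalConnectome, sigma: float = 1.0) -> np.ndarray:
    """Gaussian kernel over Euclidean distances between FC row-profiles.

    The two self-entries are excluded from each pairwise profile
    comparison (they are fixed at 1 and carry no connectivity
    information).  K_ij = exp(-d_ij^2 / (2 sigma^2)), K_ii = 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    w = fc.weights
    sq = cdist(w, w, "sqeuclidean")
    # remove the (i,i) and (j,j) column contributions from each pair:
    # both equal (1 - w_ij)^2 by symmetry and the unit diagonal
    corr = 2.0 * (1.0 - w) ** 2
    d2 = np.maximum(sq - corr, 0.0)
    k = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(k, 1.0)
    return (k + k.T) / 2.0


def diffusion_embed(affinity: np.ndarray, config: GradientConfig = GradientConfig()) -> GradientResult:
    """Eigendecompose the diffusion operator of an affinity graph.

    K' = D^-alpha K D^-alpha, P = row-normalized K'.  P is similar to
    the symmetric S = D'^-1/2 K' D'^-1/2, which is decomposed with a
    symmetric eigensolver; eigenvectors are mapped back to P's and the
    trivial constant eigenvector (eigenvalue 1) is dropped.  Component
    signs are fixed deterministically (largest-magnitude entry made
    positive); use :func:`orient_gradient` for a semantic orientation.
    """
    k = np.asarray(affinity, float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("affinity must be square")
    if np.any(k < 0):
        raise ValueError("affinity must be nonnegative")
    if not np.allclose(k, k.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    n_comp_graph, _ = connected_components(k > 0, directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp_graph} components); "
            "the Markov chain is not ergodic"
        )
    d = k.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero-degree node in affinity graph")
    inv_d_alpha = d ** (-config.alpha)
    k1 = k * np.outer(inv_d_alpha, inv_d_alpha)
    d1 = k1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    s = k1 * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    vals, vecs = np.linalg.eigh(s)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    if vals[0] > 1.0 + 1e-9:
        raise ValueError("leading eigenvalue exceeds 1: invalid Markov operator")
    # map back to eigenvectors of P and drop the trivial stationary one
    u = vecs * inv_sqrt[:, None]
    u /= np.linalg.norm(u, axis=0, keepdims=True)
    n_keep = min(config.n_components, u.shape[1] - 1)
    comps = u[:, 1 : 1 + n_keep].copy()
    eigs = vals[1 : 1 + n_keep].copy()
    for c in range(comps.shape[1]):
        peak = np.argmax(np.abs(comps[:, c]))
        if comps[peak, c] < 0:
            comps[:, c] = -comps[:, c]
    return GradientResult(components=comps, eigenvalues=eigs)


def embed_fc(fc: FunctionalConnectome, config: GradientConfig = GradientConfig()) -> GradientResult:
    """Convenience: affinity construction + diffusion embedding."""
    if config.direct_affinity:
        k = (fc.weights + 1.0) / 2.0  # shift correlations into [0, 1]
        np.fill_diagonal(k, 1.0)
    else:
        k = gaussian_affinity(fc, config.sigma)
    return diffusion_embed(k, config)


def orient_gradient(result: GradientResult, reference: np.ndarray) -> GradientResult:
    """Flip each component so it correlates positively with a
    reference map (zero correlation keeps the + sign)."""
    reference = np.asarray(reference, float)
    if reference.shape[0] != result.components.shape[0]:
        raise ValueError("reference length mismatch")
    comps = result.components.copy()
    ref_c = reference - reference.mean()
    for c in range(comps.shape[1]):
        col = comps[:, c] - comps[:, c].mean()
        corr = float(col @ ref_c)
        if corr < 0:
            comps[:, c] = -comps[:, c]
    return GradientResult(
        components=comps,
        eigenvalues=result.eigenvalues.copy(),
        orientation_reference=reference,
    )
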