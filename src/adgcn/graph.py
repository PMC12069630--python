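"""Brain-graph construction and spectral graph filtering.

A cortical mesh becomes an undirected binary graph: vertices are nodes,
triangle edges are graph edges.  Stacked graph convolutions use the
renormalized operator Â = D̃^{-1/2} Ã D̃^{-1/2} with Ã = A + I (each node
gets a self-loop so its own features survive aggregation); its spectrum
lies in [-1, 1], which keeps deep stacks numerically stable, unlike the
unnormalized I + D^{-1/2} A D^{-1/2} whose eigenvalues reach 2.

The exact spectral filter and the Chebyshev polynomial filter are kept as
verification oracles for the first-order layer used by the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg  # noqa: F401  (registered for callers)

from .io import SurfaceMesh

__all__ = [
    "BrainGraph",
    "SpectralDecomposition",
    "ChebyshevCoefficients",
    "build_adjacency",
    "adjacency_from_edges",
    "normalize_adjacency",
    "normalized_laplacian",
    "spectral_decompose",
    "exact_spectral_filter",
    "chebyshev_filter",
    "averaging_operator",
]


@dataclass
class BrainGraph:
    """Sparse graph operators for one subject's cortical mesh."""

    n_vertices: int
    adjacency: sp.csr_matrix          # A: binary, symmetric, zero diagonal
    selfloop_adjacency: sp.csr_matrix  # Ã = A + I
    degrees: np.ndarray                # D̃ diagonal (row sums of Ã)
    norm_operator: sp.csr_matrix       # Â = D̃^{-1/2} Ã D̃^{-1/2}


@dataclass
class SpectralDecomposition:
    eigenvectors: np.ndarray  # U, orthonormal columns
    eigenvalues: np.ndarray   # Λ diagonal, ascending
    lambda_max: float


@dataclass
class ChebyshevCoefficients:
    order: int
    theta: np.ndarray  # length order + 1

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64).ravel()
        if self.order < 0:
            raise ValueError("Chebyshev order must be >= 0")
        if len(self.theta) != self.order + 1:
            raise ValueError("theta must have length order + 1")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite Chebyshev coefficients")


def adjacency_from_edges(n: int, edges: np.ndarray) -> BrainGraph:
    """Build a :class:`BrainGraph` from an (E, 2) array of undirected edges."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) == 0:
        raise ValueError("cannot build graph from edgeless mesh")
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    a = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    a.data[:] = 1.0  # collapse duplicate entries to binary
    a.setdiag(0)
    a.eliminate_zeros()
    a_tilde = (a + sp.identity(n, format="csr")).tocsr()
    degrees = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(degrees))
    a_hat = (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()
    a_hat.sort_indices()
    return BrainGraph(n, a, a_tilde, degrees, a_hat)


def build_adjacency(mesh: SurfaceMesh) -> BrainGraph:
    """Mesh -> binary brain graph with self-loops and Â precomputed.

    For every face (i, j, k) the three undirected edges (i,j), (j,k),
    (i,k) enter A; duplicates across shared face edges collapse.
    """
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    return adjacency_from_edges(mesh.n_vertices, edges)


def normalize_adjacency(graph: BrainGraph) -> sp.csr_matrix:
    """Return Â = D̃^{-1/2} Ã D̃^{-1/2} (the renormalized propagation operator)."""
    return graph.norm_operator


def normalized_laplacian(graph: BrainGraph) -> sp.csr_matrix:
    """L = I - D^{-1/2} A D^{-1/2} with D the degree of A (no self-loops).

    Isolated vertices have no well-defined normalization; for them the
    self-looped degree is substituted and a warning emitted, which leaves
    the corresponding diagonal entry at 1.
    """
    a = graph.adjacency
    deg = np.asarray(a.sum(axis=1)).ravel()
    if np.any(deg == 0):
        warnings.warn("isolated vertex: using self-looped degree in Laplacian",
                      RuntimeWarning, stacklevel=2)
        deg = np.where(deg == 0, graph.degrees, deg)
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    lap = sp.identity(graph.n_vertices, format="csr") - d_inv_sqrt @ a @ d_inv_sqrt
    return lap.tocsr()


def spectral_decompose(lap: sp.spmatrix) -> SpectralDecomposition:
    """Dense eigendecomposition of a (small) normalized Laplacian."""
    dense = np.asarray(lap.todense()) if sp.issparse(lap) else np.asarray(lap)
    if dense.shape[0] > 2048:
        raise ValueError("dense decomposition restricted to n <= 2048")
    vals, vecs = np.linalg.eigh((dense + dense.T) / 2.0)
    return SpectralDecomposition(vecs, vals, float(vals[-1]))


def exact_spectral_filter(decomp: SpectralDecomposition, x: np.ndarray,
                          g) -> np.ndarray:
    """Filter a signal in the graph Fourier domain: U g(Λ) Uᵀ x."""
    x = np.asarray(x, dtype=np.float64).ravel()
    u = decomp.eigenvectors
    if len(x) != u.shape[0]:
        raise ValueError("signal length does not match decomposition")
    return u @ (np.asarray(g(decomp.eigenvalues)) * (u.T @ x))


def chebyshev_filter(graph: BrainGraph, x: np.ndarray,
                     coeffs: ChebyshevCoefficients,
                     lambda_max: float = 2.0) -> np.ndarray:
    """K-term Chebyshev filter Σ_k θ'_k T_k(L̃) x, L̃ = (2/λ_max) L - I.

    Uses the standard recurrence T_k = 2 x T_{k-1} - T_{k-2}.  The default
    λ_max = 2 is the usual upper-bound approximation for normalized
    Laplacians; pass the exact value for oracle comparisons.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if len(x) != graph.n_vertices:
        raise ValueError("signal length does not match graph")
    lap = normalized_laplacian(graph)
    l_tilde = (2.0 / lambda_max) * lap - sp.identity(graph.n_vertices, format="csr")
    t_prev = x                       # T_0(L̃) x
    out = coeffs.theta[0] * t_prev
    if coeffs.order >= 1:
        t_curr = l_tilde @ x         # T_1(L̃) x
        out = out + coeffs.theta[1] * t_curr
        for k in range(2, coeffs.order + 1):
            t_next = 2.0 * (l_tilde @ t_curr) - t_prev
            out = out + coeffs.theta[k] * t_next
            t_prev, t_curr = t_curr, t_next
    return out


def averaging_operator(graph: BrainGraph) -> sp.csr_matrix:
    """Row-stochastic smoothing operator D̃^{-1} Ã (conserves channel means
    under its stationary weighting; used by the synthetic noise generator)."""
    d_inv = sp.diags(1.0 / graph.degrees)
    return (d_inv @ graph.selfloop_adjacency).tocsr()
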