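"""Edge-vector indexing for symmetric connectivity matrices.

A connectome on ``n`` nodes has ``n*(n-1)/2`` unique edges (unordered node
pairs).  Throughout the package an edge vector stores the strict upper
triangle of the symmetric matrix in row-major order: edge 0 is (0,1),
edge 1 is (0,2), ..., edge n-2 is (0,n-1), edge n-1 is (1,2), and so on.
Node indices are 0-based internally.
"""

from __future__ import annotations

import numpy as np


class SymmetryError(ValueError):
    """Raised when a matrix expected to be symmetric is not."""


def edge_count(n_nodes: int) -> int:
    """Number of unique edges among ``n_nodes`` nodes: n*(n-1)/2."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def nodes_from_edge_count(n_edges: int) -> int:
    """Invert ``edge_count``; raises if ``n_edges`` is not triangular."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if edge_count(max(n, 2)) != n_edges:
        raise ValueError(f"{n_edges} is not n*(n-1)/2 for any integer n")
    return n


def edge_node_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint node indices (i, j) with i < j for every edge, in edge order."""
    return np.triu_indices(n_nodes, k=1)


def vectorize_edges(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Extract the strict upper triangle of a symmetric matrix as an edge vector.

    Parameters
    ----------
    matrix
        Square symmetric real matrix (n >= 2).  The diagonal is discarded.
    tol
        Maximum allowed absolute asymmetry ``|M - M.T|``.

    Returns
    -------
    1-D array of length n*(n-1)/2, upper triangle in row-major order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    asym = np.abs(matrix - matrix.T).max()
    if asym > tol:
        raise SymmetryError(f"matrix asymmetric: max |M - M.T| = {asym:g} > tol {tol:g}")
    iu, ju = np.triu_indices(n, k=1)
    return matrix[iu, ju].copy()


def restore_matrix(edge_vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an edge vector."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    expected = edge_count(n_nodes)
    if edge_vector.ndim != 1 or edge_vector.shape[0] != expected:
        raise ValueError(
            f"edge vector of length {edge_vector.shape} inconsistent with "
            f"{n_nodes} nodes (expected {expected})"
        )
    out = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    out[iu, ju] = edge_vector
    out[ju, iu] = edge_vector
    return out
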