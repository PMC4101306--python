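"""Graph-based semi-supervised learning on a Gaussian kNN similarity graph.

Nodes are patients; edge weights are ``w_ij = exp(-||z_i - z_j||^2 / alpha^2)``
between symmetrized k-nearest neighbors in the encoded feature space.  Labels
propagate by minimizing the regularized quadratic

    (f - y)' (f - y) + mu * f' L f,       L = D - W,

whose minimizer is the harmonic-style solution ``f = (I + mu L)^{-1} y``.
Because ``(I + mu L)`` is a symmetric M-matrix with unit row sums, every
``f_i`` is a convex combination of the entries of ``y`` — the maximum
principle the prediction threshold relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.io import mmread, mmwrite
from sklearn.neighbors import NearestNeighbors

from .dataset import EncodedMatrix
from .exceptions import ContractError, NumericError, ParameterError

__all__ = [
    "SimilarityGraph",
    "SSLSolution",
    "build_graph",
    "solve_ssl",
    "predict_labels",
    "class_mass_threshold",
    "save_graph",
    "load_graph",
]

#: below this size the linear system is solved densely instead of by CG
_DENSE_CUTOFF = 200


@dataclass
class SimilarityGraph:
    """Sparse symmetric similarity graph with its Laplacian pieces."""

    W: sp.csr_matrix
    k: int
    alpha: float

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def laplacian(self) -> sp.csr_matrix:
        return (sp.diags(self.degrees) - self.W).tocsr()


@dataclass
class SSLSolution:
    """Real-valued score vector with its tradeoff parameter and threshold."""

    f: np.ndarray
    mu: float
    threshold: float = 0.0


def build_graph(Z: Union[EncodedMatrix, np.ndarray], k: int, alpha: Union[float, str] = "auto") -> SimilarityGraph:
    """Build the symmetrized kNN graph with Gaussian edge weights.

    Two nodes are connected iff either is among the other's ``k`` nearest
    neighbors (union rule).  ``alpha="auto"`` sets the kernel bandwidth to
    the mean distance to the k-th nearest neighbor; duplicate rows receive
    weight-1 edges.  Self-edges are never stored.
    """
    X = Z.Z if isinstance(Z, EncodedMatrix) else np.asarray(Z, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ContractError("graph construction needs at least 2 rows")
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ParameterError(f"k must be a positive integer, got {k!r}")
    if k >= n:
        raise ParameterError(f"k must be smaller than n={n}, got {k}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)  # first column is the point itself (distance 0)
    # with exact duplicates the self-column is not guaranteed first; drop one
    # zero-distance self match per row explicitly
    rows, cols, d2 = [], [], []
    kth = np.empty(n)
    for i in range(n):
        neigh = [(dist[i, j], idx[i, j]) for j in range(k + 1) if idx[i, j] != i][:k]
        if len(neigh) < k:  # self not returned (all-duplicate corner); pad from list
            neigh = [(dist[i, j], idx[i, j]) for j in range(k + 1)][:k]
        kth[i] = neigh[-1][0]
        for dd, jj in neigh:
            rows.append(i)
            cols.append(jj)
            d2.append(dd * dd)

    if alpha == "auto":
        alpha_val = float(np.mean(kth))
        if alpha_val == 0.0:
            alpha_val = 1.0  # all points identical: any bandwidth gives weight 1
    else:
        alpha_val = float(alpha)
        if alpha_val <= 0:
            raise ParameterError(f"alpha must be positive, got {alpha!r}")

    w = np.exp(-np.asarray(d2) / alpha_val**2)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union symmetrization; weights depend only on distance
    W.setdiag(0.0)
    W.eliminate_zeros()
    return SimilarityGraph(W=W, k=int(k), alpha=alpha_val)


def solve_ssl(graph: SimilarityGraph, y: np.ndarray, mu: float, tol: float = 1e-8) -> SSLSolution:
    """Solve ``(I + mu L) f = y`` for the score vector ``f``.

    Uses a dense Cholesky-backed solve below ``n = 200`` and conjugate
    gradients on the SPD system above; ``mu = 0`` returns ``f = y`` exactly.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] != graph.n:
        raise ContractError(f"label vector length {y.shape[0]} != graph size {graph.n}")
    if mu < 0:
        raise ParameterError(f"mu must be nonnegative, got {mu}")
    if not np.all(np.isfinite(graph.W.data)):
        raise NumericError("graph weights contain non-finite values")
    if not np.any(y):
        return SSLSolution(f=np.zeros_like(y), mu=mu)
    if mu == 0:
        return SSLSolution(f=y.copy(), mu=0.0)

    L = graph.laplacian
    if graph.n < _DENSE_CUTOFF:
        A = np.eye(graph.n) + mu * L.toarray()
        f = np.linalg.solve(A, y)
    else:
        A = (sp.eye(graph.n, format="csr") + mu * L).tocsr()
        f, info = spla.cg(A, y, rtol=tol, atol=0.0, maxiter=10 * graph.n)
        if info != 0:
            raise NumericError(f"conjugate gradient did not converge (info={info})")
    if not np.all(np.isfinite(f)):
        raise NumericError("SSL solution contains non-finite values")
    return SSLSolution(f=f, mu=float(mu))


def predict_labels(sol: SSLSolution) -> np.ndarray:
    """Threshold the score vector into ``{-1, 0, +1}``; exact ties abstain."""
    f = np.asarray(sol.f)
    if not np.all(np.isfinite(f)):
        raise NumericError("scores must be finite")
    return np.sign(f - sol.threshold).astype(np.int64)


def class_mass_threshold(f: np.ndarray, positive_prior: float) -> float:
    """Threshold such that a ``positive_prior`` fraction of points score above it.

    Sorting-and-cutting variant of threshold generation: with prior ``p``,
    the top ``round(p * n)`` scores are predicted positive.  Returns the
    midpoint between the boundary scores (or an offset beyond the extremes
    when the cut is degenerate).
    """
    if not 0 < positive_prior < 1:
        raise ParameterError(f"positive_prior must be in (0, 1), got {positive_prior}")
    f = np.sort(np.asarray(f, dtype=np.float64))[::-1]
    n = f.shape[0]
    n_pos = int(round(positive_prior * n))
    if n_pos <= 0:
        return f[0] + 1.0
    if n_pos >= n:
        return f[-1] - 1.0
    return 0.5 * (f[n_pos - 1] + f[n_pos])


def save_graph(graph: SimilarityGraph, path: str | Path) -> None:
    """Export the weight matrix in Matrix Market format for inspection."""
    mmwrite(str(path), sp.coo_matrix(graph.W))


def load_graph(path: str | Path, k: int = 0, alpha: float = float("nan")) -> SimilarityGraph:
    """Re-import a weight matrix written by :func:`save_graph`."""
    W = sp.csr_matrix(mmread(str(path)))
    return SimilarityGraph(W=W, k=k, alpha=alpha)
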