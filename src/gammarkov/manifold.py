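"""Trajectory geometry in (N_GE, N_GI, H_E, H_I) space: local-PCA
dimensionality, grid entropy, locally linear embedding, and density maps.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "participation_ratio",
    "local_dimensionality",
    "trajectory_entropy",
    "lle",
    "density_mass",
]


def participation_ratio(eigenvalues: np.ndarray) -> float:
    """Dimensionality from a correlation spectrum:
    ``(sum lambda)^2 / sum lambda^2`` (equals k for k equal eigenvalues)."""
    ev = np.asarray(eigenvalues, dtype=float)
    s2 = float((ev ** 2).sum())
    if s2 == 0.0:
        return 0.0
    return float(ev.sum() ** 2 / s2)


def _standardize(points: np.ndarray) -> np.ndarray:
    std = points.std(axis=0)
    std[std == 0] = 1.0
    return (points - points.mean(axis=0)) / std


def _density_mode(z: np.ndarray, bins: int = 25) -> np.ndarray:
    """Center of the fullest cell of a coarse histogram — the 'highest
    density mass' location used to spread out the evaluation sample."""
    hist, edges = np.histogramdd(z, bins=bins)
    idx = np.unravel_index(np.argmax(hist), hist.shape)
    return np.array([(edges[d][i] + edges[d][i + 1]) / 2.0
                     for d, i in enumerate(idx)])


def local_dimensionality(points: np.ndarray, k: int = 100,
                         n_eval: int = 2000,
                         seed: int = 0) -> np.ndarray:
    """Local-PCA participation-ratio dimensionality at sampled points.

    Evaluation points are subsampled with probability proportional to the
    squared distance from the highest-density location (on per-dimension
    standardized coordinates), which evens out the otherwise very
    non-uniform trajectory density.  At each evaluation point the
    correlation matrix of the point and its ``k`` nearest neighbours is
    eigendecomposed and the participation ratio reported; dimensions that
    are constant within a neighbourhood are dropped from its correlation
    matrix.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"need more than k={k} points, got {n}")
    z = _standardize(points)
    rng = np.random.default_rng(seed)
    d2 = ((z - _density_mode(z)) ** 2).sum(axis=1)
    if d2.sum() == 0:
        eval_idx = rng.choice(n, size=min(n_eval, n), replace=False)
    else:
        p = d2 / d2.sum()
        n_pos = int((p > 0).sum())
        eval_idx = rng.choice(n, size=min(n_eval, n_pos), replace=False, p=p)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(z)
    _, idx = nbrs.kneighbors(z[eval_idx])
    dims = np.empty(eval_idx.size)
    for j in range(eval_idx.size):
        nb = points[idx[j]]  # the point itself plus k neighbours
        keep = nb.std(axis=0) > 0
        if not keep.any():
            dims[j] = 0.0
            continue
        c = np.corrcoef(nb[:, keep], rowvar=False)
        c = np.atleast_2d(c)
        ev = np.clip(np.linalg.eigvalsh(c), 0.0, None)
        dims[j] = participation_ratio(ev)
    return dims


def trajectory_entropy(points: np.ndarray, n: int = 25) -> float:
    """Occupancy entropy (bits) of the trajectory on an ``n^d`` grid.

    The bounding box of the data is split into ``n`` equal cells per
    dimension (a zero-extent dimension collapses to a single cell) and
    ``S = -sum P log2 P`` is taken over occupied cells.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("need at least one point")
    bins = []
    for d in range(points.shape[1]):
        lo, hi = points[:, d].min(), points[:, d].max()
        bins.append(np.linspace(lo, hi, n + 1) if hi > lo
                    else np.array([lo - 0.5, lo + 0.5]))
    hist, _ = np.histogramdd(points, bins=bins)
    p = hist.ravel() / points.shape[0]
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def lle(points: np.ndarray, k: int = 20, d: int = 3,
        reg: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Locally linear embedding into ``d`` dimensions.

    Three steps: (1) k-nearest-neighbour graph; (2) reconstruction weights
    minimizing ``||x_i - sum_j W_ij x_j||^2`` with each row of ``W``
    summing to 1 (regularized local Gram solve); (3) embedding minimizing
    the same quadratic form, subject to zero mean and identity sample
    covariance — the bottom non-constant eigenvectors of
    ``(I - W)^T (I - W)`` scaled by ``sqrt(n)``.

    Returns ``(Y, eigenvalues)``: the ``(n, d)`` embedding and the
    ascending eigenvalues (reconstruction costs) of its components.
    Raises if the neighbourhood graph is disconnected.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if not (n > k > d):
        raise ValueError("need n_points > k_neighbors > d_components")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X)
    graph = nbrs.kneighbors_graph(X, mode="connectivity")
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"k-nearest-neighbour graph has {n_comp} components; "
            "raise k to connect the point cloud"
        )
    idx = nbrs.kneighbors(X, return_distance=False)[:, 1:]
    W = np.zeros((n, k))
    ones = np.ones(k)
    for i in range(n):
        Z = X[idx[i]] - X[i]
        G = Z @ Z.T
        trace = np.trace(G)
        G.flat[:: k + 1] += reg * (trace if trace > 0 else 1.0)
        w = np.linalg.solve(G, ones)
        W[i] = w / w.sum()
    Wsp = sp.csr_matrix(
        (W.ravel(), (np.repeat(np.arange(n), k), idx.ravel())), shape=(n, n)
    )
    M = (sp.eye(n) - Wsp).T @ (sp.eye(n) - Wsp)
    # bottom eigenvectors; the constant vector (eigenvalue ~0) is dropped
    vals, vecs = spla.eigsh(M.tocsc(), k=d + 1, sigma=-1e-6, which="LM")
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    Y = vecs[:, 1:d + 1] * np.sqrt(n)
    Y = Y - Y.mean(axis=0)
    # fix the sign convention: largest-magnitude entry positive
    for j in range(Y.shape[1]):
        if Y[np.argmax(np.abs(Y[:, j])), j] < 0:
            Y[:, j] = -Y[:, j]
    return Y, np.clip(vals[1:d + 1], 0.0, None)


def density_mass(points: np.ndarray, dims, bins=25, ranges=None,
                 weights: np.ndarray | None = None):
    """Normalized occupancy histogram over selected coordinates.

    ``dims`` selects the coordinates (indices or the names
    ``N_GE``/``N_GI``/``H_E``/``H_I``); optional ``weights`` (e.g. a
    stationary distribution over states) make the histogram a probability
    mass map.  Returns ``(hist, edges)`` with total mass 1.
    """
    names = {"N_GE": 0, "N_GI": 1, "H_E": 2, "H_I": 3}
    dims = [names[d] if isinstance(d, str) else int(d) for d in dims]
    pts = np.asarray(points, dtype=float)[:, dims]
    hist, edges = np.histogramdd(pts, bins=bins, range=ranges,
                                 weights=weights)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, edges
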