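"""Deterministic synthetic inputs for testing statistics and solvers
without running the network simulators."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .cg import CTMCGenerator
from .containers import SpikeTrain

__all__ = [
    "make_sync_train",
    "make_poisson_train",
    "make_burst_train",
    "make_planar_cloud",
    "make_gaussian_cloud",
    "make_toy_chain",
]


def _pops(neurons: np.ndarray, n_e: int) -> np.ndarray:
    return (neurons >= n_e).astype(np.uint8)


def make_sync_train(n: int = 100, period: float = 20.0,
                    T: float = 1000.0, n_e: int | None = None) -> SpikeTrain:
    """Fully synchronized train: all ``n`` neurons spike at every multiple
    of ``period`` up to ``T``."""
    if period <= 0:
        raise ValueError("period must be positive")
    ticks = np.arange(period, T + 1e-9, period)
    times = np.repeat(ticks, n)
    neurons = np.tile(np.arange(n), ticks.size)
    n_e = n if n_e is None else n_e
    return SpikeTrain(times, neurons, _pops(neurons, n_e), n, T, n_e)


def make_poisson_train(n: int, rate: float, T: float,
                       seed: int, n_e: int | None = None) -> SpikeTrain:
    """Independent homogeneous Poisson trains at ``rate`` Hz per neuron."""
    if n <= 0 or rate < 0 or T <= 0:
        raise ValueError("need positive n and T and non-negative rate")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * T / 1000.0, size=n)
    neurons = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, T, size=counts.sum())
    order = np.argsort(times, kind="stable")
    n_e = n if n_e is None else n_e
    return SpikeTrain(times[order], neurons[order],
                      _pops(neurons[order], n_e), n, T, n_e)


def make_burst_train(burst_size: int, period: float, T: float,
                     n: int = 100, jitter: float = 0.0,
                     seed: int = 0) -> SpikeTrain:
    """Bursts of ``burst_size`` spikes every ``period`` ms on a silent
    background (neurons ``0..burst_size-1`` fire in each burst)."""
    if burst_size <= 0 or burst_size > n or period <= 0:
        raise ValueError("need 0 < burst_size <= n and period > 0")
    rng = np.random.default_rng(seed)
    ticks = np.arange(period, T + 1e-9, period)
    times = np.repeat(ticks, burst_size)
    if jitter > 0:
        times = times + rng.uniform(0, jitter, size=times.size)
    neurons = np.tile(np.arange(burst_size), ticks.size)
    order = np.argsort(times, kind="stable")
    return SpikeTrain(times[order], neurons[order],
                      _pops(neurons[order], n), n, T, n)


def make_planar_cloud(n: int, noise: float = 0.01,
                      seed: int = 0) -> np.ndarray:
    """Points on a random 2-D affine subspace of 4-D, with isotropic
    Gaussian noise of standard deviation ``noise`` times the cloud extent."""
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.normal(size=(4, 2)))
    uv = rng.uniform(-1.0, 1.0, size=(n, 2))
    pts = uv @ basis.T
    extent = pts.max() - pts.min()
    return pts + rng.normal(scale=noise * extent, size=pts.shape)


def make_gaussian_cloud(n: int, seed: int = 0, dim: int = 4) -> np.ndarray:
    """Isotropic standard-normal sample in ``dim`` dimensions."""
    return np.random.default_rng(seed).normal(size=(n, dim))


def make_toy_chain(rates) -> CTMCGenerator:
    """Small CTMC from an explicit off-diagonal rate matrix.

    ``rates[i][j]`` is the transition rate i -> j; the diagonal is
    ignored and rebuilt as minus the row sum.  For the 2-state chain with
    rates alpha (1->2) and beta (2->1) the stationary law is
    ``(beta, alpha) / (alpha + beta)``.
    """
    A = np.asarray(rates, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("rates must be a square matrix")
    np.fill_diagonal(A, 0.0)
    if (A < 0).any():
        raise ValueError("rates must be non-negative")
    Q = sp.csr_matrix(A - np.diag(A.sum(axis=1)))
    return CTMCGenerator(Q=Q, shape=(A.shape[0],))
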