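"""Coarse-grained (CG) model: the four-variable Markov chain
``(N_GE, N_GI, H_E, H_I)``, its sparse generator, the shrunk (SCG) lumping,
and invariant distributions.

All per-neuron pending pools are merged into two network pools ``H_E``,
``H_I``; a fixed fraction ``a_EE`` of the E pool sits on E neurons (and is
consumed at rate ``1/tau_EE``), the remainder on I neurons (rate
``1/tau_IE``).  Kick effects flip the gate counts with the learned
count-conditioned probabilities; a firing event decrements the gate count
and adds the mean recipient count ``M_E``/``M_I`` to the matching pool.
From any interior state at most 12 distinct non-self transitions exist:
four external flip/fire moves, five pending-E moves, three pending-I moves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from . import _kernels
from ._kernels import (
    K_E_B_E, K_E_B_I, K_E_G_E, K_E_G_I,
    K_EXT_B_E, K_EXT_B_I, K_EXT_G_E, K_EXT_G_I,
    K_I_G_E, K_I_G_I,
)
from .containers import CGProjection, SpikeTrain
from .params import NetworkParameters, derive_couplings
from .rn import TransitionTable

__all__ = [
    "CGState",
    "CGResult",
    "CTMCGenerator",
    "transitions_from",
    "run_cg",
    "run_scg",
    "build_generator",
    "stationary_distribution",
    "marginal_density",
    "scg_lift",
    "scg_project",
]

#: refuse to enumerate truncated boxes larger than this many states
DEFAULT_STATE_LIMIT = 4_000_000


@dataclass(frozen=True)
class CGState:
    n_ge: int
    n_gi: int
    h_e: int
    h_i: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_ge, self.n_gi, self.h_e, self.h_i)


def _rate_terms(state, params, table, coup):
    """The 12 (target-change, rate) pairs from one state, uncapped.

    Changes are (d_nge, d_ngi, d_he, d_hi); pool increments use the
    deterministic integer mean recipient counts.
    """
    n_ge, n_gi, h_e, h_i = state
    P = table.dense()
    n_e, n_i = params.N_E, params.N_I
    nbe, nbi = n_e - n_ge, n_i - n_gi
    lam_e, lam_i = params.lambda_E / 1000.0, params.lambda_I / 1000.0
    de, di = coup.M_E_int, coup.M_I_int
    terms = [
        # external kick takes effect
        ((1, 0, 0, 0), P[K_EXT_B_E, nbe] * nbe * lam_e),
        ((0, 1, 0, 0), P[K_EXT_B_I, nbi] * nbi * lam_i),
        ((-1, 0, de, 0), P[K_EXT_G_E, n_ge] * n_ge * lam_e),
        ((0, -1, 0, di), P[K_EXT_G_I, n_gi] * n_gi * lam_i),
        # one E-kick takes effect
        ((1, 0, -1, 0),
         P[K_E_B_E, nbe] * coup.a_EE * (nbe / n_e) * h_e / params.tau_EE),
        ((0, 1, -1, 0),
         P[K_E_B_I, nbi] * coup.a_IE * (nbi / n_i) * h_e / params.tau_IE),
        ((-1, 0, de - 1, 0),
         P[K_E_G_E, n_ge] * coup.a_EE * (n_ge / n_e) * h_e / params.tau_EE),
        ((0, -1, -1, di),
         P[K_E_G_I, n_gi] * coup.a_IE * (n_gi / n_i) * h_e / params.tau_IE),
        ((0, 0, -1, 0),
         ((1 - P[K_E_B_E, nbe]) * coup.a_EE * (nbe / n_e) / params.tau_EE
          + (1 - P[K_E_B_I, nbi]) * coup.a_IE * (nbi / n_i) / params.tau_IE
          + (1 - P[K_E_G_E, n_ge]) * coup.a_EE * (n_ge / n_e) / params.tau_EE
          + (1 - P[K_E_G_I, n_gi]) * coup.a_IE * (n_gi / n_i) / params.tau_IE
          ) * h_e),
        # one I-kick takes effect
        ((-1, 0, 0, -1),
         P[K_I_G_E, n_ge] * coup.a_EI * (n_ge / n_e) * h_i / params.tau_I),
        ((0, -1, 0, -1),
         P[K_I_G_I, n_gi] * coup.a_II * (n_gi / n_i) * h_i / params.tau_I),
        ((0, 0, 0, -1),
         (1 - P[K_I_G_E, n_ge] * coup.a_EI * (n_ge / n_e)
          - P[K_I_G_I, n_gi] * coup.a_II * (n_gi / n_i)) * h_i / params.tau_I),
    ]
    return terms


def transitions_from(state, params: NetworkParameters, table: TransitionTable,
                     caps: tuple[int, int] | None = None):
    """All non-self transitions from one CG state.

    Returns ``(targets, self_rate)`` where ``targets`` is a list of
    ``(CGState, rate_per_ms)`` with positive rates, and ``self_rate`` is the
    total rate of no-change events (external kicks that neither flip nor
    fire).  With ``caps`` the truncated chain is used: transitions past a
    pool cap have rate zero.
    """
    if isinstance(state, CGState):
        state = state.as_tuple()
    n_ge, n_gi, h_e, h_i = state
    coup = derive_couplings(params)
    if table.raw.min() < -1e-12 or table.raw.max() > 1 + 1e-12:
        raise ValueError("transition-table probabilities outside [0, 1]")
    P = table.dense()
    targets = []
    for (d_nge, d_ngi, d_he, d_hi), rate in _rate_terms(state, params, table, coup):
        if rate <= 0:
            continue
        tgt = (n_ge + d_nge, n_gi + d_ngi, h_e + d_he, h_i + d_hi)
        if tgt[0] < 0 or tgt[0] > params.N_E or tgt[1] < 0 or tgt[1] > params.N_I:
            continue
        if tgt[2] < 0 or tgt[3] < 0:
            continue
        if caps is not None and (tgt[2] > caps[0] or tgt[3] > caps[1]):
            continue  # boundary rule: cap-exceeding transitions get rate 0
        targets.append((CGState(*tgt), float(rate)))
    # self rate: external kicks with no flip
    nbe, nbi = params.N_E - n_ge, params.N_I - n_gi
    self_rate = (
        (1 - P[K_EXT_B_E, nbe]) * nbe * params.lambda_E / 1000.0
        + (1 - P[K_EXT_B_I, nbi]) * nbi * params.lambda_I / 1000.0
        + (1 - P[K_EXT_G_E, n_ge]) * n_ge * params.lambda_E / 1000.0
        + (1 - P[K_EXT_G_I, n_gi]) * n_gi * params.lambda_I / 1000.0
    )
    return targets, float(self_rate)


@dataclass
class CGResult:
    train: SpikeTrain  # mock raster: spikes assigned to random neurons
    projection: CGProjection
    spike_times: np.ndarray
    spike_pops: np.ndarray


def run_cg(params: NetworkParameters, table: TransitionTable, T: float,
           seed: int, traj_stride: float = 1.0,
           caps: tuple[int, int] | None = None,
           increment: str = "stochastic",
           initial: tuple[int, int, int, int] = (0, 0, 0, 0)) -> CGResult:
    """Event-driven simulation of the CG chain for ``T`` ms.

    ``increment`` selects how a spike expands its pool: ``"stochastic"``
    rounds the fractional mean recipient count ``M_E``/``M_I`` by a
    Bernoulli draw (expectation-preserving), ``"int"`` uses the fixed
    round-half-up integers that the generator uses.  With ``caps`` the
    truncated chain is simulated (integer increments are then required so
    the simulated process matches the generator exactly).

    Each firing event is one population spike; the mock raster assigns it
    to a uniformly random neuron of that population.
    """
    if increment not in ("stochastic", "int"):
        raise ValueError("increment must be 'stochastic' or 'int'")
    if caps is not None and increment == "stochastic":
        raise ValueError("a capped (truncated) simulation requires integer "
                         "pool increments")
    coup = derive_couplings(params)
    rng = np.random.default_rng(seed)
    cap_e, cap_i = (-1, -1) if caps is None else (int(caps[0]), int(caps[1]))
    out = _kernels.cg_kernel(
        rng, float(T), params.N_E, params.N_I,
        params.lambda_E, params.lambda_I,
        params.tau_EE, params.tau_IE, params.tau_I,
        coup.a_EE, coup.a_IE, coup.a_EI, coup.a_II,
        coup.M_E, coup.M_I, coup.M_E_int, coup.M_I_int,
        increment == "stochastic", cap_e, cap_i,
        table.dense(), float(traj_stride),
        int(initial[0]), int(initial[1]), int(initial[2]), int(initial[3]),
    )
    spk_t, spk_pop, samp_t, s_nge, s_ngi, s_he, s_hi = out
    # mock raster: uniformly random neuron of the spiking population
    neurons = np.where(
        spk_pop == 0,
        rng.integers(0, params.N_E, size=spk_t.size),
        params.N_E + rng.integers(0, params.N_I, size=spk_t.size),
    ).astype(np.int64)
    train = SpikeTrain(times=spk_t, neurons=neurons,
                       pops=spk_pop.astype(np.uint8),
                       n_neurons=params.N, duration=float(T), n_e=params.N_E)
    proj = CGProjection(samp_t, s_nge, s_ngi, s_he, s_hi)
    return CGResult(train, proj, spk_t, spk_pop.astype(np.uint8))


# ---------------------------------------------------------------------------
# shrunk CG (SCG) lumping


def scg_lift(h_scg: int, K: int) -> float:
    """Lift a lumped pool count to the mid-point of its CG cell.

    Cell ``h`` covers the K raw counts ``((h-1)K, hK]`` and lifts to
    ``(h - 0.5) K``; the empty pool lifts to 0 and ``K = 1`` is the exact
    identity.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if K == 1 or h_scg == 0:
        return float(h_scg)
    return (h_scg - 0.5) * K


def scg_project(change: int, K: int, rng: np.random.Generator) -> int:
    """Project a raw pool change onto the lumped scale.

    ``y = floor(x/K) + Bernoulli(x/K - floor(x/K))``, so the expected
    projected change is exactly ``x / K``.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    y = math.floor(change / K)
    p = change / K - y
    if p > 0 and rng.random() < p:
        y += 1
    return y


def run_scg(params: NetworkParameters, table: TransitionTable, T: float,
            seed: int, K: int, traj_stride: float = 1.0,
            initial: tuple[int, int, int, int] = (0, 0, 0, 0)):
    """Simulate the shrunk CG chain: lumped pools of cell size ``K``.

    At each step the lumped state is lifted to mid-cell raw pools, the CG
    rates are evaluated there, one transition is sampled, and its pool
    changes are projected back with the expectation-preserving Bernoulli
    rounding.  Returns ``(spike_times, spike_pops, CGProjection)``.
    """
    coup = derive_couplings(params)
    P = table.dense()
    rng = np.random.default_rng(seed)
    n_ge, n_gi, hse, hsi = map(int, initial)
    spk_t, spk_pop = [], []
    samp = []
    next_s, t = 0.0, 0.0
    while True:
        lifted = (n_ge, n_gi, scg_lift(hse, K), scg_lift(hsi, K))
        terms = _rate_terms(lifted, params, table, coup)
        rates = np.array([max(r, 0.0) for _, r in terms])
        rtot = rates.sum()
        if rtot <= 0:
            break
        t_new = t + rng.exponential(1.0 / rtot)
        while next_s <= T and next_s < t_new:
            samp.append((next_s, n_ge, n_gi, hse, hsi))
            next_s += traj_stride
        if t_new > T:
            break
        t = t_new
        k = int(rng.choice(12, p=rates / rtot))
        (d_nge, d_ngi, d_he, d_hi), _ = terms[k]
        n_ge += d_nge
        n_gi += d_ngi
        if d_he:
            hse = max(hse + scg_project(d_he, K, rng), 0)
        if d_hi:
            hsi = max(hsi + scg_project(d_hi, K, rng), 0)
        if k in (2, 6):
            spk_t.append(t)
            spk_pop.append(0)
        elif k in (3, 7):
            spk_t.append(t)
            spk_pop.append(1)
    while next_s <= T:
        samp.append((next_s, n_ge, n_gi, hse, hsi))
        next_s += traj_stride
    samp = np.array(samp) if samp else np.empty((0, 5))
    proj = CGProjection(samp[:, 0], samp[:, 1], samp[:, 2],
                        samp[:, 3], samp[:, 4])
    return np.array(spk_t), np.array(spk_pop, dtype=np.uint8), proj


# ---------------------------------------------------------------------------
# generator matrix and invariant distribution


@dataclass
class CTMCGenerator:
    """Sparse rate matrix over the truncated CG box with its state indexer.

    ``shape`` is ``(N_E+1, N_I+1, cap_E+1, cap_I+1)``; state ``(g, i, e, h)``
    maps to row ``ravel_multi_index((g, i, e, h), shape)``.  Off-diagonals
    are transition rates per ms, the diagonal is minus the row sum.
    """

    Q: sp.csr_matrix
    shape: tuple[int, int, int, int]

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def state_index(self, state) -> int:
        if isinstance(state, CGState):
            state = state.as_tuple()
        return int(np.ravel_multi_index(state, self.shape))

    def index_state(self, idx: int) -> CGState:
        return CGState(*np.unravel_index(idx, self.shape))

    def states(self) -> np.ndarray:
        """(n_states, 4) array of state coordinates in row order."""
        return np.column_stack(
            np.unravel_index(np.arange(self.n_states), self.shape)
        )


def build_generator(params: NetworkParameters, table: TransitionTable,
                    caps: tuple[int, int],
                    state_limit: int = DEFAULT_STATE_LIMIT) -> CTMCGenerator:
    """Enumerate the truncated box and assemble the sparse generator.

    Transitions that would exceed a pool cap are assigned rate zero
    (truncation, not clipping), so probability never leaks out of the box.
    Pool increments are the deterministic round-half-up integers.
    """
    coup = derive_couplings(params)
    cap_e, cap_i = int(caps[0]), int(caps[1])
    shape = (params.N_E + 1, params.N_I + 1, cap_e + 1, cap_i + 1)
    n_states = int(np.prod(shape))
    if n_states > state_limit:
        raise MemoryError(
            f"truncated box has {n_states} states, above the configured "
            f"limit of {state_limit}; shrink the caps or lump with the SCG"
        )
    P = table.dense()
    nge, ngi, he, hi = [a.ravel() for a in np.indices(shape)]
    nbe, nbi = params.N_E - nge, params.N_I - ngi
    lam_e, lam_i = params.lambda_E / 1000.0, params.lambda_I / 1000.0
    n_e, n_i = params.N_E, params.N_I
    de, di = coup.M_E_int, coup.M_I_int

    changes = [
        (1, 0, 0, 0), (0, 1, 0, 0), (-1, 0, de, 0), (0, -1, 0, di),
        (1, 0, -1, 0), (0, 1, -1, 0), (-1, 0, de - 1, 0), (0, -1, -1, di),
        (0, 0, -1, 0), (-1, 0, 0, -1), (0, -1, 0, -1), (0, 0, 0, -1),
    ]
    rates = [
        P[K_EXT_B_E, nbe] * nbe * lam_e,
        P[K_EXT_B_I, nbi] * nbi * lam_i,
        P[K_EXT_G_E, nge] * nge * lam_e,
        P[K_EXT_G_I, ngi] * ngi * lam_i,
        P[K_E_B_E, nbe] * coup.a_EE * (nbe / n_e) * he / params.tau_EE,
        P[K_E_B_I, nbi] * coup.a_IE * (nbi / n_i) * he / params.tau_IE,
        P[K_E_G_E, nge] * coup.a_EE * (nge / n_e) * he / params.tau_EE,
        P[K_E_G_I, ngi] * coup.a_IE * (ngi / n_i) * he / params.tau_IE,
        ((1 - P[K_E_B_E, nbe]) * coup.a_EE * (nbe / n_e) / params.tau_EE
         + (1 - P[K_E_B_I, nbi]) * coup.a_IE * (nbi / n_i) / params.tau_IE
         + (1 - P[K_E_G_E, nge]) * coup.a_EE * (nge / n_e) / params.tau_EE
         + (1 - P[K_E_G_I, ngi]) * coup.a_IE * (ngi / n_i) / params.tau_IE
         ) * he,
        P[K_I_G_E, nge] * coup.a_EI * (nge / n_e) * hi / params.tau_I,
        P[K_I_G_I, ngi] * coup.a_II * (ngi / n_i) * hi / params.tau_I,
        (1 - P[K_I_G_E, nge] * coup.a_EI * (nge / n_e)
         - P[K_I_G_I, ngi] * coup.a_II * (ngi / n_i)) * hi / params.tau_I,
    ]
    rows, cols, vals = [], [], []
    for (d0, d1, d2, d3), rate in zip(changes, rates):
        rate = np.maximum(np.asarray(rate, dtype=float), 0.0)
        tge, tgi = nge + d0, ngi + d1
        the, thi = he + d2, hi + d3
        ok = ((rate > 0)
              & (tge >= 0) & (tge <= params.N_E)
              & (tgi >= 0) & (tgi <= params.N_I)
              & (the >= 0) & (the <= cap_e)
              & (thi >= 0) & (thi <= cap_i))
        if not ok.any():
            continue
        src = np.nonzero(ok)[0]
        tgt = np.ravel_multi_index(
            (tge[ok], tgi[ok], the[ok], thi[ok]), shape)
        rows.append(src)
        cols.append(tgt)
        vals.append(rate[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return CTMCGenerator(Q=Q.tocsr(), shape=shape)


def _recurrent_class(Q: sp.csr_matrix, start: int) -> np.ndarray:
    """Indices of the recurrent (terminal strongly connected) class
    reached from ``start``."""
    adj = (abs(Q) > 0).astype(np.int8)
    adj.setdiag(0)
    n_comp, labels = csgraph.connected_components(adj, connection="strong")
    if n_comp == 1:
        return np.arange(Q.shape[0])
    # terminal components have no edges leaving them
    coo = adj.tocoo()
    leaving = np.zeros(n_comp, dtype=bool)
    cross = labels[coo.row] != labels[coo.col]
    leaving[np.unique(labels[coo.row[cross]])] = True
    reach = csgraph.breadth_first_order(adj, start, return_predecessors=False)
    reachable_terminal = [c for c in np.unique(labels[reach]) if not leaving[c]]
    if not reachable_terminal:
        raise RuntimeError("no recurrent class reachable from the start state")
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(reachable_terminal, key=lambda c: sizes[c])
    warnings.warn(
        "generator is reducible; restricting to the recurrent class "
        f"({sizes[best]} of {Q.shape[0]} states)", stacklevel=3,
    )
    return np.nonzero(labels == best)[0]


def stationary_distribution(gen, start: int = 0,
                            tol: float = 1e-12) -> np.ndarray:
    """Invariant probability vector of a CTMC generator.

    Accepts a :class:`CTMCGenerator` or a raw sparse/dense rate matrix.
    Works on the recurrent class reached from ``start`` (warning if the
    chain is reducible; other entries are zero).  Computed from the leading
    left eigenvector of the uniformized matrix ``P = I + Q/Lambda`` and
    polished by power iteration until ``||pi Q||_inf`` is at machine level
    relative to ``Lambda``.
    """
    Q = gen.Q if isinstance(gen, CTMCGenerator) else sp.csr_matrix(gen)
    n = Q.shape[0]
    keep = _recurrent_class(Q, start)
    Qr = Q[np.ix_(keep, keep)] if keep.size < n else Q
    m = Qr.shape[0]
    if m == 1:
        pi_r = np.ones(1)
    elif m <= 3:
        # dense null space for tiny chains
        import scipy.linalg as sla
        ns = sla.null_space(Qr.toarray().T)
        pi_r = np.abs(ns[:, 0])
        pi_r /= pi_r.sum()
    else:
        lam = float(np.max(-Qr.diagonal())) * 1.0001 + 1e-12
        P = sp.eye(m, format="csr") + Qr.tocsr() / lam
        PT = P.T.tocsr()
        v0 = np.full(m, 1.0 / m)
        try:
            w, vec = spla.eigs(PT, k=1, which="LM", v0=v0, tol=1e-14,
                               maxiter=50 * m)
            pi_r = np.abs(np.real(vec[:, 0]))
        except spla.ArpackNoConvergence:
            pi_r = v0.copy()
        pi_r /= pi_r.sum()
        # power polish: cheap and guards against a spurious Arnoldi vector
        resid = np.abs(pi_r @ Qr).max()
        it = 0
        while resid > tol * lam and it < 20000:
            for _ in range(50):
                pi_r = PT @ pi_r
            pi_r = np.abs(pi_r)
            pi_r /= pi_r.sum()
            resid = np.abs(pi_r @ Qr).max()
            it += 50
    pi = np.zeros(n)
    pi[keep] = pi_r
    pi = np.maximum(pi, 0.0)
    return pi / pi.sum()


def marginal_density(pi: np.ndarray, shape: tuple[int, ...],
                     dims) -> np.ndarray:
    """Marginal of a probability vector over the kept coordinate ``dims``.

    ``dims`` are indices into ``(N_GE, N_GI, H_E, H_I)`` (or names).  Mass
    is conserved exactly.
    """
    names = {"N_GE": 0, "N_GI": 1, "H_E": 2, "H_I": 3}
    dims = [names[d] if isinstance(d, str) else int(d) for d in dims]
    arr = np.asarray(pi).reshape(shape)
    drop = tuple(i for i in range(len(shape)) if i not in dims)
    out = arr.sum(axis=drop)
    # order axes as requested
    kept_sorted = sorted(dims)
    perm = [kept_sorted.index(d) for d in dims]
    return np.transpose(out, axes=perm) if out.ndim > 1 else out
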