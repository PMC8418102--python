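"""Full model: exact event-driven simulation of the Markovian
integrate-and-fire (MIF) network.

Each neuron carries an integer membrane potential ``v`` on
``{V_I, ..., V_th}`` or the refractory token ``R``, plus two pending-kick
pools ``H_i^E``, ``H_i^I``.  External Poisson kicks raise ``v`` by one
level; each pending E-kick raises ``v`` by the synaptic strength after an
exponential delay; each pending I-kick lowers ``v`` by the voltage-scaled
decrement ``(v - V_I)/(V_th - V_I) * S`` (realized as an integer by
stochastic rounding).  A neuron reaching ``V_th`` fires, delivers kicks to
each neuron's pool by an independent coin flip, and dwells in ``R`` for an
exponential refractory time before resetting to ``V_r``.

The simulation is an exact exponential race over all event categories
(external arrivals, pending-kick consumptions, refractory exits), as
implemented in :mod:`gammarkov._kernels`.  The scalar kick primitives below
mirror the kernel's single-neuron update rules and are the reference for
its unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .containers import CGProjection, SpikeTrain
from .params import NetworkParameters

__all__ = [
    "R",
    "MIFNetworkState",
    "MIFResult",
    "EventLog",
    "run_mif",
    "project_cg",
    "total_event_rates",
    "apply_external_kick",
    "apply_e_kick",
    "apply_i_kick",
    "fire",
    "exit_refractory",
    "pending_pool_trace",
]

#: Distinguished refractory token for scalar membrane potentials.
R = "R"


@dataclass
class MIFNetworkState:
    """Mutable network state: per-neuron potentials and pending pools.

    ``v[i]`` is meaningful only where ``refractory[i]`` is False; a
    refractory neuron is in the token state ``R``.
    """

    v: np.ndarray  # int levels
    refractory: np.ndarray  # bool
    h_e: np.ndarray  # per-neuron pending-E pools
    h_i: np.ndarray  # per-neuron pending-I pools
    t: float  # ms

    @classmethod
    def at_rest(cls, params: NetworkParameters) -> "MIFNetworkState":
        n = params.N
        return cls(
            v=np.full(n, params.V_r, dtype=np.int64),
            refractory=np.zeros(n, dtype=bool),
            h_e=np.zeros(n, dtype=np.int64),
            h_i=np.zeros(n, dtype=np.int64),
            t=0.0,
        )

    def potential(self, i: int):
        return R if self.refractory[i] else int(self.v[i])


@dataclass
class EventLog:
    """Per-kick-effect records: key code, conditioning count, flip outcome.

    Key codes are the constants in :mod:`gammarkov._kernels`; the
    conditioning count is the pre-event base (for base targets) or gate
    (for gate targets) count of the target's population.
    """

    keys: np.ndarray
    counts: np.ndarray
    outcomes: np.ndarray
    v_c: int
    n_e: int
    n_i: int

    def __len__(self) -> int:
        return self.keys.size


@dataclass
class MIFResult:
    train: SpikeTrain
    projection: CGProjection
    events: EventLog | None
    #: pool bookkeeping: delivered/consumed kick counts and final pool sums
    bookkeeping: dict


def _internal_check(state: MIFNetworkState) -> None:
    if (state.h_e < 0).any() or (state.h_i < 0).any():
        raise RuntimeError("negative pending-kick pool: corrupt state")


def total_event_rates(state: MIFNetworkState, params: NetworkParameters) -> dict:
    """Per-category event rates (per ms) for the exponential race."""
    _internal_check(state)
    n_e = params.N_E
    is_e = np.arange(params.N) < n_e
    ref = state.refractory
    rates = {
        "external": (n_e * params.lambda_E + params.N_I * params.lambda_I) / 1000.0,
        "pending_e_on_e": float(state.h_e[is_e].sum()) / params.tau_EE,
        "pending_e_on_i": float(state.h_e[~is_e].sum()) / params.tau_IE,
        "pending_i": float(state.h_i.sum()) / params.tau_I,
        "refractory_exit": (ref[is_e].sum() / params.tau_R_E
                            + ref[~is_e].sum() / params.tau_R_I),
    }
    rates["total"] = float(sum(rates.values()))
    return rates


def apply_external_kick(v, params: NetworkParameters):
    """One external kick: ``v -> v + 1``; no effect on a refractory neuron.

    Returns ``(v', fired)``; a neuron reaching ``V_th`` fires and enters R.
    """
    if v == R:
        return R, False
    v2 = v + 1
    if v2 >= params.V_th:
        return R, True
    return v2, False


def apply_e_kick(v, s_qe: int, params: NetworkParameters):
    """One recurrent E-kick of strength ``s_qe``: ``v -> v + s_qe``."""
    if v == R:
        return R, False
    v2 = v + s_qe
    if v2 >= params.V_th:
        return R, True
    return v2, False


def apply_i_kick(v, s_qi: int, params: NetworkParameters, rng: np.random.Generator):
    """One recurrent I-kick: voltage-scaled decrement, stochastic rounding.

    The ideal decrement is ``(v - V_I)/(V_th - V_I) * s_qi``; it is realized
    as its floor plus a Bernoulli draw on the fractional part, so the
    expected decrement is exact and ``v`` never drops below ``V_I``.
    """
    if v == R:
        return R
    dstar = (v - params.V_I) / (params.V_th - params.V_I) * s_qi
    d = math.floor(dstar)
    if rng.random() < dstar - d:
        d += 1
    return max(v - d, params.V_I)


def fire(neuron_id: int, state: MIFNetworkState, params: NetworkParameters,
         rng: np.random.Generator) -> dict:
    """Spike delivery: the neuron enters R and every neuron's pool receives
    a kick by an independent coin flip (autapses permitted).

    Returns the delivered-kick counts ``{"E": ..., "I": ...}`` by target
    population.
    """
    n_e = params.N_E
    is_e_target = np.arange(params.N) < n_e
    state.refractory[neuron_id] = True
    state.v[neuron_id] = params.V_r
    if neuron_id < n_e:
        p = np.where(is_e_target, params.P_EE, params.P_IE)
        hit = rng.random(params.N) < p
        state.h_e[hit] += 1
    else:
        p = np.where(is_e_target, params.P_EI, params.P_II)
        hit = rng.random(params.N) < p
        state.h_i[hit] += 1
    return {"E": int(hit[is_e_target].sum()), "I": int(hit[~is_e_target].sum())}


def exit_refractory(neuron_id: int, state: MIFNetworkState,
                    params: NetworkParameters) -> int:
    """Refractory exit: reset to the rest potential ``V_r``."""
    if not state.refractory[neuron_id]:
        raise RuntimeError(f"neuron {neuron_id} is not refractory")
    state.refractory[neuron_id] = False
    state.v[neuron_id] = params.V_r
    return params.V_r


def project_cg(state: MIFNetworkState, v_c: int,
               n_e: int) -> tuple[int, int, int, int]:
    """Project a network state to ``(N_GE, N_GI, H_E, H_I)``.

    A neuron is a gate neuron iff it is not refractory and ``v >= V_c``;
    refractory neurons count as base.
    """
    gate = (~state.refractory) & (state.v >= v_c)
    is_e = np.arange(state.v.size) < n_e
    return (
        int(gate[is_e].sum()),
        int(gate[~is_e].sum()),
        int(state.h_e.sum()),
        int(state.h_i.sum()),
    )


def run_mif(params: NetworkParameters, T: float, seed: int,
            record_events: bool = False,
            traj_stride: float = 1.0) -> MIFResult:
    """Simulate the MIF network for ``T`` ms from the all-rest state.

    Identical ``(params, T, seed)`` yield identical output.  The
    coarse-grained projection is sampled every ``traj_stride`` ms; with
    ``record_events`` the kick-effect log needed by the reduced-network
    estimator is returned as well.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    rng = np.random.default_rng(seed)
    out = _kernels.mif_kernel(
        rng, float(T), params.N_E, params.N_I,
        params.V_I, params.V_r, params.V_th, params.V_c,
        params.S_EE, params.S_IE, params.S_EI, params.S_II,
        params.P_EE, params.P_IE, params.P_EI, params.P_II,
        params.lambda_E, params.lambda_I,
        params.tau_EE, params.tau_IE, params.tau_I,
        params.tau_R_E, params.tau_R_I,
        float(traj_stride), record_events,
    )
    (spk_t, spk_id, samp_t, s_nge, s_ngi, s_he, s_hi,
     log_key, log_cnt, log_out, inc_e, cons_e, inc_i, cons_i,
     he_final, hi_final) = out
    train = SpikeTrain(
        times=spk_t, neurons=spk_id,
        pops=(spk_id >= params.N_E).astype(np.uint8),
        n_neurons=params.N, duration=float(T), n_e=params.N_E,
    )
    proj = CGProjection(samp_t, s_nge, s_ngi, s_he, s_hi)
    events = None
    if record_events:
        events = EventLog(log_key, log_cnt, log_out,
                          v_c=params.V_c, n_e=params.N_E, n_i=params.N_I)
    bookkeeping = {
        "e_kicks_delivered": int(inc_e), "e_kicks_consumed": int(cons_e),
        "i_kicks_delivered": int(inc_i), "i_kicks_consumed": int(cons_i),
        "h_e_final": int(he_final), "h_i_final": int(hi_final),
    }
    return MIFResult(train, proj, events, bookkeeping)


def pending_pool_trace(kick_times: np.ndarray, tau: float,
                       sample_times: np.ndarray, n_runs: int,
                       seed: int) -> np.ndarray:
    """Ensemble traces of one pending-kick pool fed by a fixed kick train.

    Each presynaptic kick arriving at ``kick_times[k]`` stays in the pool
    for an independent Exp(``tau``) holding time, exactly as in the MIF
    pending-pool mechanism.  Returns an ``(n_runs, len(sample_times))``
    array of pool sizes; its ensemble mean converges to the exponential
    Green's-function convolution ``sum_k exp(-(t - t_k)/tau)`` of the
    conductance it replaces.
    """
    rng = np.random.default_rng(seed)
    kick_times = np.asarray(kick_times, dtype=float)
    sample_times = np.asarray(sample_times, dtype=float)
    lifetimes = rng.exponential(tau, size=(n_runs, kick_times.size))
    # pool size at t = number of kicks with t_k <= t < t_k + lifetime
    arrived = kick_times[None, :, None] <= sample_times[None, None, :]
    alive = (kick_times[None, :, None] + lifetimes[:, :, None]
             > sample_times[None, None, :])
    return (arrived & alive).sum(axis=1)
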