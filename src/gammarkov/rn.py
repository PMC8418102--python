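"""Reduced network (RN): two-state neurons with learned flip probabilities.

The RN keeps the MIF's pending-pool and external-drive machinery but
collapses each membrane potential to a base/gate label relative to the
cutoff ``V_c``.  The flip probability of a kick-effect event is learned
from MIF simulations as a conditional frequency: for each kick class
(external, E, I), target population and pre-state, the empirical flip
fraction is tabulated as a function of the pre-event base count (for base
targets) or gate count (for gate targets) of that population — the
conditional-expectation closure of the reduction.

Structurally, a gate neuron flipped down by an upward (external or E) kick
*fires* — it delivers recurrent kicks exactly as in the MIF — whereas an
I-kick flips gate to base silently.  I-kicks never act on base neurons.
Refractory dynamics are folded into the base state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import (
    K_E_B_E, K_E_B_I, K_E_G_E, K_E_G_I,
    K_EXT_B_E, K_EXT_B_I, K_EXT_G_E, K_EXT_G_I,
    K_I_G_E, K_I_G_I, N_KEYS,
)
from .containers import CGProjection, SpikeTrain
from .mif import EventLog
from .params import NetworkParameters

__all__ = ["KEYS", "TransitionTable", "estimate_table", "run_rn"]

#: (kick class, pre-state, target population) for each key code.
KEYS: list[tuple[str, str, str]] = [
    ("ext", "B", "E"), ("ext", "B", "I"), ("ext", "G", "E"), ("ext", "G", "I"),
    ("E", "B", "E"), ("E", "B", "I"), ("E", "G", "E"), ("E", "G", "I"),
    ("I", "G", "E"), ("I", "G", "I"),
]

KEY_INDEX = {k: i for i, k in enumerate(KEYS)}

#: below this sample count an estimate is smoothed over neighbouring counts
SMOOTH_MIN_SAMPLES = 30
SMOOTH_HALF_WIDTH = 2


@dataclass
class TransitionTable:
    """Count-conditioned flip probabilities for all ten kick keys.

    ``raw[key, c]`` is the empirical flip frequency at conditioning count
    ``c`` and ``n_samples[key, c]`` the number of logged events behind it.
    ``dense()`` returns the smoothed/imputed probabilities the simulators
    use; ``imputed`` marks entries that were filled by interpolation or
    edge extrapolation rather than observed.
    """

    n_e: int
    n_i: int
    v_c: int
    raw: np.ndarray  # (N_KEYS, max_count + 1) float
    n_samples: np.ndarray  # (N_KEYS, max_count + 1) int64
    _dense: np.ndarray | None = field(default=None, repr=False)
    _imputed: np.ndarray | None = field(default=None, repr=False)

    @property
    def max_count(self) -> int:
        return self.raw.shape[1] - 1

    def _pop_size(self, key: int) -> int:
        return self.n_e if KEYS[key][2] == "E" else self.n_i

    def dense(self) -> np.ndarray:
        """Smoothed, gap-filled probability array ``P[key, count]``."""
        if self._dense is None:
            self._dense, self._imputed = self._build_dense()
        return self._dense

    @property
    def imputed(self) -> np.ndarray:
        self.dense()
        return self._imputed

    def _build_dense(self) -> tuple[np.ndarray, np.ndarray]:
        dense = np.zeros_like(self.raw)
        imputed = np.zeros(self.raw.shape, dtype=bool)
        for k in range(N_KEYS):
            m = self._pop_size(k)
            raw = self.raw[k, : m + 1]
            ns = self.n_samples[k, : m + 1]
            visited = ns > 0
            est = raw.copy()
            # moving-average smoothing where the count is thinly sampled
            for c in np.nonzero(visited & (ns < SMOOTH_MIN_SAMPLES))[0]:
                lo = max(0, c - SMOOTH_HALF_WIDTH)
                hi = min(m, c + SMOOTH_HALF_WIDTH)
                win = slice(lo, hi + 1)
                wn = ns[win]
                if wn.sum() > 0:
                    est[c] = float((raw[win] * wn).sum() / wn.sum())
            # gap filling: linear interpolation between visited counts,
            # constant extrapolation at the edges
            idx = np.nonzero(visited)[0]
            counts = np.arange(m + 1)
            if idx.size == 0:
                dense[k, : m + 1] = 0.0
                imputed[k, : m + 1] = True
                continue
            dense[k, : m + 1] = np.interp(counts, idx, est[idx])
            imputed[k, : m + 1] = ~visited
        return np.clip(dense, 0.0, 1.0), imputed

    def lookup(self, kick: str, pre_state: str, pop: str, count: int) -> float:
        """Smoothed flip probability for one key at one conditioning count.

        Counts outside the tabulated range use the nearest tabulated value.
        """
        k = KEY_INDEX[(kick, pre_state, pop)]
        m = self._pop_size(k)
        c = min(max(int(count), 0), m)
        return float(self.dense()[k, c])

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        entries = {}
        for k, key in enumerate(KEYS):
            m = self._pop_size(k)
            entries["/".join(key)] = {
                "probability": self.raw[k, : m + 1].tolist(),
                "n_samples": self.n_samples[k, : m + 1].tolist(),
            }
        return {"n_e": self.n_e, "n_i": self.n_i, "v_c": self.v_c,
                "keys": entries}

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionTable":
        n_e, n_i = int(d["n_e"]), int(d["n_i"])
        width = max(n_e, n_i) + 1
        raw = np.zeros((N_KEYS, width))
        ns = np.zeros((N_KEYS, width), dtype=np.int64)
        for k, key in enumerate(KEYS):
            e = d["keys"]["/".join(key)]
            p = np.asarray(e["probability"], dtype=float)
            raw[k, : p.size] = p
            ns[k, : p.size] = np.asarray(e["n_samples"], dtype=np.int64)
        return cls(n_e=n_e, n_i=n_i, v_c=int(d["v_c"]), raw=raw, n_samples=ns)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "TransitionTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_probabilities(cls, n_e: int, n_i: int, v_c: int,
                           prob: np.ndarray,
                           n_samples: int = 10**6) -> "TransitionTable":
        """Build a fully-specified table from a given probability array
        (used for synthetic chains and tests)."""
        width = max(n_e, n_i) + 1
        prob = np.asarray(prob, dtype=float)
        if prob.shape != (N_KEYS, width):
            raise ValueError(f"prob must have shape {(N_KEYS, width)}")
        ns = np.full((N_KEYS, width), n_samples, dtype=np.int64)
        return cls(n_e=n_e, n_i=n_i, v_c=v_c, raw=prob.copy(), n_samples=ns)


def estimate_table(events: EventLog, v_c: int | None = None) -> TransitionTable:
    """Estimate the flip-probability table from MIF kick-effect logs.

    Each entry is the empirical flip frequency among logged events sharing
    the same key and conditioning count.  Raises on an empty log or on a
    cutoff mismatch between log and request.
    """
    if len(events) == 0:
        raise ValueError("empty event log: nothing to estimate from")
    if v_c is not None and v_c != events.v_c:
        raise ValueError(
            f"event log was recorded with V_c={events.v_c}, requested {v_c}"
        )
    width = max(events.n_e, events.n_i) + 1
    flat = events.keys.astype(np.int64) * width + events.counts.astype(np.int64)
    n = np.bincount(flat, minlength=N_KEYS * width).reshape(N_KEYS, width)
    k = np.bincount(flat, weights=events.outcomes.astype(float),
                    minlength=N_KEYS * width).reshape(N_KEYS, width)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    return TransitionTable(n_e=events.n_e, n_i=events.n_i, v_c=events.v_c,
                           raw=raw, n_samples=n.astype(np.int64))


def run_rn(params: NetworkParameters, table: TransitionTable, T: float,
           seed: int, traj_stride: float = 1.0
           ) -> tuple[SpikeTrain, CGProjection]:
    """Simulate the two-state reduced network for ``T`` ms.

    The event race is the MIF's, with refractory dynamics folded into the
    base state; kick effects flip base/gate labels with the table's
    count-conditioned probabilities.
    """
    if table.n_e != params.N_E or table.n_i != params.N_I:
        raise ValueError("transition table population sizes do not match params")
    rng = np.random.default_rng(seed)
    out = _kernels.rn_kernel(
        rng, float(T), params.N_E, params.N_I,
        params.P_EE, params.P_IE, params.P_EI, params.P_II,
        params.lambda_E, params.lambda_I,
        params.tau_EE, params.tau_IE, params.tau_I,
        table.dense(), float(traj_stride),
    )
    spk_t, spk_id, samp_t, s_nge, s_ngi, s_he, s_hi = out
    train = SpikeTrain(
        times=spk_t, neurons=spk_id,
        pops=(spk_id >= params.N_E).astype(np.uint8),
        n_neurons=params.N, duration=float(T), n_e=params.N_E,
    )
    return train, CGProjection(samp_t, s_nge, s_ngi, s_he, s_hi)
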