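"""Shared data containers: spike trains and coarse-grained trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "CGProjection", "POP_E", "POP_I"]

POP_E = 0
POP_I = 1


@dataclass
class SpikeTrain:
    """Timestamped, neuron-labelled spike records, time-sorted.

    ``pops`` holds 0 for excitatory and 1 for inhibitory spikes. The
    container also carries the network size and the simulated duration so
    that rate and density statistics are well defined even for empty trains.
    """

    times: np.ndarray  # ms, non-decreasing
    neurons: np.ndarray  # int ids in [0, n_neurons)
    pops: np.ndarray  # 0 = E, 1 = I
    n_neurons: int
    duration: float  # ms
    n_e: int | None = None  # excitatory population size, if known

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        self.pops = np.asarray(self.pops, dtype=np.uint8)
        if not (self.times.shape == self.neurons.shape == self.pops.shape):
            raise ValueError("times, neurons and pops must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.times.size and (
            self.neurons.min() < 0 or self.neurons.max() >= self.n_neurons
        ):
            raise ValueError("neuron ids must lie in [0, n_neurons)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def select(self, pop: int) -> "SpikeTrain":
        """Sub-train of one population (0 = E, 1 = I)."""
        m = self.pops == pop
        return SpikeTrain(
            self.times[m], self.neurons[m], self.pops[m],
            self.n_neurons, self.duration, self.n_e,
        )

    def shifted(self, dt: float) -> "SpikeTrain":
        """The same train with every spike time shifted by ``dt`` ms."""
        return SpikeTrain(
            self.times + dt, self.neurons.copy(), self.pops.copy(),
            self.n_neurons, self.duration, self.n_e,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.n_neurons == other.n_neurons
            and np.isclose(self.duration, other.duration)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.neurons, other.neurons)
            and np.array_equal(self.pops, other.pops)
        )


@dataclass
class CGProjection:
    """Sampled coarse-grained trajectory ``(t, N_GE, N_GI, H_E, H_I)``.

    ``N_GE``/``N_GI`` count gate neurons (potential at or above the cutoff
    ``V_c``; refractory neurons count as base); ``H_E``/``H_I`` are the
    network-wide pending-kick pool sizes.
    """

    times: np.ndarray
    n_ge: np.ndarray
    n_gi: np.ndarray
    h_e: np.ndarray
    h_i: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        for name in ("n_ge", "n_gi", "h_e", "h_i"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.times.size

    def as_points(self) -> np.ndarray:
        """(n, 4) float array of ``(N_GE, N_GI, H_E, H_I)`` samples."""
        return np.column_stack(
            [self.n_ge, self.n_gi, self.h_e, self.h_i]
        ).astype(np.float64)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CGProjection):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("times", "n_ge", "n_gi", "h_e", "h_i")
        )
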