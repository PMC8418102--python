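"""Network parameters, regime presets, and derived coupling constants.

The model is a homogeneous random network of ``N_E`` excitatory and ``N_I``
inhibitory Markovian integrate-and-fire neurons.  Membrane potentials live on
the integer lattice ``{V_I, ..., V_th}`` plus a distinguished refractory
token, external drive is Poissonian, and recurrent spikes act through
"pending-kick pools" consumed after exponential delays.  Three canonical
regimes -- homogeneous ("Hom"), regular ("Reg"), and synchronized ("Syn") --
differ only in the excitatory synaptic time scales ``(tau_EE, tau_IE)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

__all__ = [
    "NetworkParameters",
    "DerivedCouplings",
    "REGIMES",
    "make_regime",
    "derive_couplings",
    "validate",
    "membrane_state_count",
]


@dataclass(frozen=True)
class NetworkParameters:
    """All model constants of the spiking network.

    Voltages are dimensionless integer levels (one level = one external
    kick), times are in milliseconds and external rates in events per
    second per neuron.  ``S_EI``/``S_II`` are the inhibitory kick sizes
    *before* the voltage-dependent scaling applied at kick time.
    """

    N_E: int = 75
    N_I: int = 25
    V_I: int = -66
    V_r: int = 0
    V_th: int = 100
    #: gate cutoff: a neuron with v >= V_c is a "gate" neuron, i.e. only a
    #: couple of E-kicks away from threshold.
    V_c: int = 60
    S_EE: int = 20
    S_IE: int = 8
    S_EI: int = 20
    S_II: int = 20
    P_EE: float = 0.15
    P_IE: float = 0.5
    P_EI: float = 0.5
    P_II: float = 0.4
    lambda_E: float = 7000.0
    lambda_I: float = 7000.0
    tau_EE: float = 1.4
    tau_IE: float = 1.2
    tau_I: float = 4.5
    tau_R_E: float = 2.5
    tau_R_I: float = 2.5

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    def replace(self, **kwargs) -> "NetworkParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParameters":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NetworkParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: The three canonical regimes differ only in (tau_EE, tau_IE).
REGIMES: dict[str, dict[str, float]] = {
    "Hom": {"tau_EE": 4.0, "tau_IE": 1.2},
    "Reg": {"tau_EE": 1.7, "tau_IE": 1.2},
    "Syn": {"tau_EE": 1.4, "tau_IE": 1.2},
}


class ConfigurationError(ValueError):
    """Raised for invalid parameter sets or unknown regime labels."""


def make_regime(name: str, overrides: dict | None = None, **kwargs) -> NetworkParameters:
    """Return the printed parameter set for a named regime.

    Parameters
    ----------
    name
        One of ``"Hom"``, ``"Reg"``, ``"Syn"``, or a key of *overrides*.
    overrides
        Optional user-supplied table of extra regime presets,
        ``{label: {field: value, ...}}``.
    kwargs
        Individual field overrides applied on top of the preset.
    """
    table = dict(REGIMES)
    if overrides:
        table.update(overrides)
    if name not in table:
        raise ConfigurationError(
            f"unknown regime {name!r}; known regimes: {sorted(table)}"
        )
    params = NetworkParameters(**table[name])
    if kwargs:
        params = params.replace(**kwargs)
    violations = validate(params)
    if violations:
        raise ConfigurationError("; ".join(violations))
    return params


@dataclass(frozen=True)
class DerivedCouplings:
    """Pool-allocation fractions and mean recipient counts.

    ``a_EE`` is the fraction of the network pending-E pool residing on E
    neurons (``a_IE`` on I neurons); ``a_EI``/``a_II`` are the analogous
    fractions of the pending-I pool.  ``M_E``/``M_I`` are the mean numbers
    of postsynaptic recipients of one E/I spike; the ``_int`` variants are
    their round-half-up integers used as fixed pool increments by the
    coarse-grained generator.
    """

    a_EE: float
    a_IE: float
    a_EI: float
    a_II: float
    M_E: float
    M_I: float
    M_E_int: int
    M_I_int: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def derive_couplings(params: NetworkParameters) -> DerivedCouplings:
    """Compute allocation fractions and mean recipient counts.

    ``a_EE = P_EE N_E / (P_EE N_E + P_IE N_I)`` and
    ``M_E = P_EE N_E + P_IE N_I`` (similarly for the inhibitory side).
    """
    m_e = params.P_EE * params.N_E + params.P_IE * params.N_I
    m_i = params.P_EI * params.N_E + params.P_II * params.N_I
    if m_e <= 0 or m_i <= 0:
        raise ConfigurationError(
            "all connection probabilities of one spike type are zero; "
            "allocation fractions are undefined"
        )
    a_ee = params.P_EE * params.N_E / m_e
    a_ei = params.P_EI * params.N_E / m_i
    return DerivedCouplings(
        a_EE=a_ee,
        a_IE=1.0 - a_ee,
        a_EI=a_ei,
        a_II=1.0 - a_ei,
        M_E=m_e,
        M_I=m_i,
        M_E_int=_round_half_up(m_e),
        M_I_int=_round_half_up(m_i),
    )


def validate(params: NetworkParameters) -> list[str]:
    """Return a list of invariant violations (empty iff valid)."""
    v: list[str] = []
    if params.N_E <= 0:
        v.append("N_E must be positive")
    if params.N_I <= 0:
        v.append("N_I must be positive")
    if not (params.V_I < params.V_r < params.V_c < params.V_th):
        v.append("voltage levels must satisfy V_I < V_r < V_c < V_th")
    for name in ("P_EE", "P_IE", "P_EI", "P_II"):
        p = getattr(params, name)
        if not 0.0 <= p <= 1.0:
            v.append(f"{name}={p} outside [0, 1]")
    for name in ("S_EE", "S_IE", "S_EI", "S_II"):
        if getattr(params, name) <= 0:
            v.append(f"{name} must be positive")
    for name in ("tau_EE", "tau_IE", "tau_I", "tau_R_E", "tau_R_I"):
        if getattr(params, name) <= 0:
            v.append(f"{name} must be positive")
    for name in ("lambda_E", "lambda_I"):
        if getattr(params, name) < 0:
            v.append(f"{name} must be non-negative")
    return v


def membrane_state_count(params: NetworkParameters) -> int:
    """Size of the per-neuron voltage state space: the integer levels
    ``V_I..V_th`` plus the refractory token."""
    return params.V_th - params.V_I + 1 + 1
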