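"""Shared fixtures: one long synchronized-regime simulation and the
transition table trained from it are reused across the suite."""

import numpy as np
import pytest

from gammarkov import make_regime
from gammarkov.mif import run_mif
from gammarkov.rn import TransitionTable, estimate_table


@pytest.fixture(scope="session")
def syn_params():
    return make_regime("Syn")


@pytest.fixture(scope="session")
def syn_run(syn_params):
    """10-s Syn-regime MIF run with the kick-effect event log."""
    return run_mif(syn_params, 10_000.0, seed=7, record_events=True)


@pytest.fixture(scope="session")
def syn_table(syn_run):
    """Transition table trained on the 10-s Syn run."""
    return estimate_table(syn_run.events)


@pytest.fixture(scope="session")
def small_net():
    """A small network and a fully-specified synthetic flip table, for
    chain-level tests where the exact probabilities do not matter."""
    params = make_regime("Syn").replace(N_E=8, N_I=3)
    prob = np.zeros((10, 9))
    prob[0:4] = 0.01   # external flips / fires
    prob[4:6] = 0.2    # E-kick base->gate
    prob[6:8] = 0.3    # E-kick gate fires
    prob[8:10] = 0.5   # I-kick gate->base
    table = TransitionTable.from_probabilities(8, 3, 60, prob)
    return params, table
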