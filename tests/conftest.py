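import numpy as np
import pandas as pd
import pytest

import entrainkit as ek
from entrainkit import oscillator as osc


@pytest.fixture(scope="session")
def exp1_small():
    """Two-participant Experiment-1 table with moderate effects."""
    cfg = ek.DesignConfig(experiment="exp1", n_participants=2, seed=11)
    table, truth = ek.simulate_exp1(n_participants=2, seed=11, config=cfg)
    return table, truth


@pytest.fixture(scope="session")
def model_sweep():
    """Full (omega, k, drive frequency) entrainment-change sweep, shared
    across tests since it is the expensive cached object."""
    return osc.sweep(dt_out=0.02)


def make_phase_table(rng, n, binning, p_fn, phase_col="fm_phase"):
    """Trial table with phases drawn from bin centers and Bernoulli outcomes
    from an arbitrary probability function of phase."""
    idx = rng.integers(0, binning.n_bins, n)
    phases = binning.bin_centers[idx]
    p = p_fn(phases)
    acc = (rng.random(n) < p).astype(int)
    return pd.DataFrame({
        "participant_id": 0,
        "session_id": 1,
        "condition": 1.0,
        "tacs_condition": "active",
        phase_col: phases,
        "accuracy": acc,
    })
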