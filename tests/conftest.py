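"""Shared fixtures: small synthetic experiments reused across test modules.

Session-scoped so each simulated dataset is generated once per test run.
"""

import pytest

from wmcap.synthetic import GenerativeConfig, gen_experiment, make_neurons
from wmcap.task import SpikeTable


@pytest.fixture(scope="session")
def small_config():
    return GenerativeConfig(
        n_sessions=3, trials_per_session=320, tuning_gain=10.0, rng_seed=42
    )


@pytest.fixture(scope="session")
def carrying_experiment(small_config):
    """Color-selective neurons with equal normalization weights."""
    neurons = make_neurons(small_config, 9, "carrying")
    trials, trains = gen_experiment(small_config, neurons, seed=42)
    return trials, SpikeTable(trains), neurons


@pytest.fixture(scope="session")
def fav_map(carrying_experiment):
    _, _, neurons = carrying_experiment
    return {n.neuron_id: n.favorite_location for n in neurons}


@pytest.fixture(scope="session")
def behavior_trials():
    """Larger trial-only dataset for behavioral statistics (no spikes)."""
    from wmcap.synthetic import gen_behavior, gen_trials

    cfg = GenerativeConfig(n_sessions=40, trials_per_session=320, rng_seed=7)
    all_trials = []
    next_id = 0
    for s in range(cfg.n_sessions):
        ts = gen_trials(cfg, cfg.trials_per_session, 7, session_id=s)
        for t in ts:
            t.trial_id += next_id
        next_id += len(ts)
        all_trials.extend(gen_behavior(ts, cfg, 7 + s + 1))
    return all_trials
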