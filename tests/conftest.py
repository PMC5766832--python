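import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import whisklearn as wl
from whisklearn import behavior, synthetic


@pytest.fixture(scope="session")
def small_scenario():
    """A 2-mouse, 3-day detection cohort small enough for I/O tests."""
    return wl.detection_scenario(n_mice=2, n_days=3, trials_per_session=30,
                                 seed=11)


@pytest.fixture(scope="session")
def small_session(small_scenario):
    """One classified session with LFP and spikes."""
    meta, trials = synthetic.simulate_behavior(small_scenario)[0]
    perf = behavior.session_performance(trials, day_index=meta.day_index)
    lfp = synthetic.simulate_lfp(trials, small_scenario, perf.dprime,
                                 np.random.default_rng(5))
    units = synthetic.simulate_spikes(trials, small_scenario,
                                      np.random.default_rng(6))
    return meta, trials, lfp, units


@pytest.fixture(scope="session")
def trained_session():
    """A trained-day session (high d') with realistic trial counts,
    shared across SEP/ROC tests to amortize the simulation cost."""
    sc = wl.detection_scenario(n_mice=1, n_days=8, trials_per_session=200,
                               seed=3)
    rng = synthetic._rng(sc, "behavior", 0, 8)
    trials = synthetic._simulate_detection_session(sc, rng, day=8)
    perf = behavior.session_performance(trials, day_index=8)
    lfp = synthetic.simulate_lfp(trials, sc, perf.dprime,
                                 synthetic._rng(sc, "lfp", 0, 8))
    return sc, trials, perf, lfp
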