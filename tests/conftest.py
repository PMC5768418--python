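import numpy as np
import pandas as pd
import pytest

import meaphys as m


@pytest.fixture(scope="session")
def control_session():
    """One simulated control-male session shared across tests."""
    cfg = m.control_male_config(seed=11)
    population = m.make_population(cfg)
    events = m.make_schedule(cfg)
    spikes = m.simulate_spike_trains(population, events, cfg)
    return cfg, population, events, spikes


@pytest.fixture()
def toy_spikes_events():
    """Three hand-checkable units, two stimuli, three trials each.

    Onsets at 100, 200 (stim A) interleaved with 150, 250 (stim B) plus a
    third trial of each; unit u2 is silent.
    """
    events = pd.DataFrame(
        {
            "stimulus": ["A", "B", "A", "B", "A", "B"],
            "onset_s": [100.0, 200.0, 300.0, 400.0, 500.0, 600.0],
            "rep_index": [1, 1, 2, 2, 3, 3],
        }
    )
    # u0: one spike 10 s before and two in the 40 s after every onset
    u0 = np.sort(
        np.concatenate(
            [events.onset_s - 10, events.onset_s + 5, events.onset_s + 15]
        )
    )
    # u1: steady 1 Hz background
    u1 = np.arange(0.5, 660.0, 1.0)
    spikes = pd.DataFrame(
        {
            "unit_id": ["u0"] * len(u0) + ["u1"] * len(u1),
            "spike_time_s": np.concatenate([u0, u1]),
        }
    )
    return spikes, events
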