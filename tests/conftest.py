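import numpy as np
import pytest

from cardiogate import siggen


@pytest.fixture
def default_config():
    return siggen.SimulationConfig(n_cycles=60, rr_mean=900.0, rr_sd=50.0, seed=0)


@pytest.fixture
def clean_schedule(default_config):
    return siggen.draw_cycle_schedule(default_config)


@pytest.fixture(scope="session")
def session_200():
    """A 200-cycle default session with ground truth (shared; read-only)."""
    cfg = siggen.SimulationConfig(n_cycles=200, rr_mean=900.0, rr_sd=50.0, seed=0)
    log, truth = siggen.simulate_session_with_truth(cfg)
    return cfg, log, truth


def match_offsets_ms(trigger_times, event_times, window_ms=150.0):
    """Offsets (ms) of triggers to their nearest ground-truth event."""
    event_times = np.asarray(event_times)
    out = []
    for t in np.asarray(trigger_times):
        i = int(np.argmin(np.abs(event_times - t)))
        d = (t - event_times[i]) * 1000.0
        if abs(d) <= window_ms:
            out.append(d)
    return np.asarray(out)
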