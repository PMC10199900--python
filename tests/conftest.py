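import numpy as np
import pytest

import porecall as pc


@pytest.fixture(scope="session")
def library():
    return pc.default_library()


@pytest.fixture(scope="session")
def g4_run():
    """Small simulated glycine run (Device #4 model): ~300 events with
    detection and ground-truth labels; reused across tests."""
    frame, truth, trace = pc.simulate_events(("G", "Device #4"), 300, seed=7)
    return frame, truth, trace


def make_encoded(populations, n_per_class, seed, L=48, noise=0.01):
    """Synthetic encoded events straight from per-class blockade models:
    a rectangular normalised waveform at depth ~ N(mean, sd) plus the
    matching scalar features.  Fast path for classifier tests."""
    rng = np.random.default_rng(seed)
    out = []
    for label, (mean, sd) in populations.items():
        depth = np.clip(rng.normal(mean, sd, n_per_class), 1e-4, 1.0)
        dwell = np.exp(rng.normal(np.log(5e-4), 0.6, n_per_class))
        for d, dt in zip(depth, dwell):
            vec = np.ones(L)
            vec[L // 4: 3 * L // 4] = 1.0 - d
            vec += rng.normal(0, noise, L)
            out.append(pc.EncodedEvent(np.clip(vec, -0.2, 1.2),
                                       (float(d), float(np.log10(dt))),
                                       label=label))
    return out


@pytest.fixture
def encoded_ga():
    """Balanced encoded G/A populations at the published Device #4
    separation."""
    return make_encoded({"G": (0.229, 0.016), "A": (0.295, 0.021)},
                        n_per_class=250, seed=11)
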