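import numpy as np
import pytest

import eodsort as es


@pytest.fixture(scope="session")
def short_dyad():
    """A 20 s well-separated synthetic dyad shared by the fast tests."""
    recording, truth = es.easy_dyad(3, duration_s=20.0)
    return recording, truth


@pytest.fixture(scope="session")
def detected(short_dyad):
    recording, _ = short_dyad
    events, waveforms = es.detect_and_extract(recording)
    return events, waveforms


@pytest.fixture(scope="session")
def two_fish_waveforms():
    """Noisy normalized snippets of two divergent fish, 150 per fish.

    Built directly from the fish templates plus additive noise (no full
    recording), centered like the extraction stage would produce them.
    """
    rng = np.random.default_rng(7)
    out = {}
    for fish, seed in (("A", 11), ("B", 12)):
        model = es.make_fish(seed, 0.9)
        template = es.template_waveform(model, 50_000.0)
        rows = []
        for _ in range(150):
            y = np.zeros(31)
            peak = int(np.argmax(np.abs(template)))
            lo = 15 - peak
            y[lo: lo + template.size] = template
            y += rng.normal(0, 0.01, 31)
            extremum = y[np.argmax(np.abs(y))]
            y = y / abs(extremum) * (1 if extremum > 0 else -1)
            rows.append(y)
        out[fish] = np.stack(rows)
    return out
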