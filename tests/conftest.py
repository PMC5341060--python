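import numpy as np
import pytest

import voicelaws as vl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_signal():
    """A modest synthetic voiced signal shared across tests (read-only)."""
    spec = vl.SynthSpec(event_count=1500, seed=101)
    series, gt = vl.synth_voice_signal(spec)
    return spec, series, gt


def make_events(energies, durations_s=None, rate=1.0, theta=50.0):
    """Build an EventSequence with prescribed token energies/durations,
    for tests that exercise symbolization/laws without a real signal."""
    energies = np.asarray(energies, dtype=float)
    if durations_s is None:
        durations_s = np.ones_like(energies)
    tokens = []
    pos = 0
    for e, d in zip(energies, durations_s):
        n = max(int(round(d * rate)), 1)
        tokens.append(vl.Token(pos, n, n / rate, float(e)))
        pos += n + 1
    return vl.EventSequence(
        threshold=vl.ThresholdSpec(theta, 0.0),
        tokens=tokens,
        silences=[],
        series_length=pos,
        rate=rate,
    )
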