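import numpy as np
import pytest

import vasodyn as v


def brute_amplitude_spectrum(x: np.ndarray, fs: float):
    """O(N^2) DFT oracle: one-sided amplitude spectrum 2|X_k|/N."""
    x = np.asarray(x, dtype=float)
    n = x.size
    ks = np.arange(n // 2 + 1)
    grid = np.exp(-2j * np.pi * np.outer(ks, np.arange(n)) / n)
    amp = 2.0 * np.abs(grid @ x) / n
    freqs = ks * fs / n
    return freqs, amp


@pytest.fixture
def pure_sine_trace():
    """300 s, 2 Hz trace with a 0.05-relative-amplitude 0.1 Hz sinusoid."""
    trace, truth = v.gen_diameter_trace(
        v.TraceSimConfig(
            duration=300.0, sampling_rate=2.0, vasomotion_amplitude=0.05,
            vasomotion_frequency=0.1,
        )
    )
    return trace, truth


@pytest.fixture
def cardiac_trace():
    """20 s, 200 Hz trace with a 0.02-relative cardiac sinusoid at 10 Hz."""
    trace, truth = v.gen_diameter_trace(
        v.TraceSimConfig(
            duration=20.0, sampling_rate=200.0, vasomotion_amplitude=0.0,
            cardiac_amplitude=0.02, cardiac_frequency=10.0,
        )
    )
    return trace, truth
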