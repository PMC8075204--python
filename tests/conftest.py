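"""Shared fixtures and oracle constructions for the voltspike test suite."""

from __future__ import annotations

import numpy as np
import pytest

import voltspike as vs

FRAME_RATE = 400.0


def make_planted_trace(
    seed: int,
    T: int = 4000,
    amp: float = 10.0,
    rate: float = FRAME_RATE,
    clip: float = 3.0,
    delta: bool = False,
):
    """Planted-spike oracle trace: known spikes in bounded noise.

    Biexponential waveform spikes (peak height ``amp``) at the detector's
    target ISI statistics (uniform 0.1-0.2 s gaps) on Gaussian noise
    truncated at ``clip`` sd. Truncation gives a deterministic separation
    margin between noise peaks and spikes, so exact-recovery assertions
    test the detector rather than the luck of the noise draw. Returns
    ``(trace, spike_frames)`` with spike frames at the waveform peaks.
    """
    rng = np.random.default_rng(seed)
    noise = np.clip(rng.standard_normal(T), -clip, clip)
    lo, hi = int(0.1 * rate), int(0.2 * rate)
    gaps = rng.integers(lo, hi + 1, size=T // lo)
    s = 40 + np.cumsum(gaps)
    s = s[s < T - 40]
    x = noise.copy()
    if delta:
        x[s] += amp
    else:
        t = np.arange(0, 12)
        k = np.exp(-t / 2.0) - np.exp(-t / 1.0)
        off = int(np.argmax(k))
        k = k / k.max()
        for i in s:
            x[i - off : i - off + len(k)] += amp * k
    return x, s


def spike_f1(detected, truth, rate=FRAME_RATE, window=0.010):
    """F1 of detected vs true spike frames under 10 ms greedy matching."""
    m = vs.match_spikes_greedy(
        np.asarray(detected) / rate, np.asarray(truth) / rate, window
    )
    return m.f1


@pytest.fixture(scope="session")
def small_sim():
    """One small 2-neuron simulated movie shared by pipeline tests."""
    cfg = vs.SimConfig(
        n_neurons=2, fov=(46, 46), duration=10.0, spike_amplitude=0.15, seed=11
    )
    movie, gt = vs.simulate_movie(cfg)
    return cfg, movie, gt
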