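import numpy as np
import pytest

from alphadrift import SimulationConfig, draw_subject_truth, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def short_config():
    """10-s trials keep generator-dependent tests fast."""
    return SimulationConfig(trial_duration=10.0, seed=42)


@pytest.fixture(scope="session")
def short_trial(short_config):
    st = draw_subject_truth(short_config, 0)
    return generate_trial(short_config, st, 1)


def hann_dft_band_db(window, fs, low, high):
    """Brute-force oracle for the online alpha estimator: explicit DFT sum
    with Hann coefficients, density scaling, one-sided doubling, and
    inclusive band-edge bin averaging."""
    n = len(window)
    w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))  # symmetric
    xw = window * w
    k = np.arange(n // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n) @ xw
    psd = (np.abs(dft) ** 2) / (fs * np.sum(w ** 2))
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = k * fs / n
    sel = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    return 10.0 * np.log10(np.mean(psd[sel]))


def welch_hamming_oracle(x, fs, bands):
    """Brute-force Welch oracle: explicit segmentation at L = floor(2N/9),
    50% overlap, Hamming taper, periodogram averaging, inclusive edges."""
    n = len(x)
    L = int(np.floor(2 * n / 9))
    hop = L - L // 2
    m = np.arange(L)
    w = 0.54 - 0.46 * np.cos(2 * np.pi * m / (L - 1))
    k = np.arange(L // 2 + 1)
    dftmat = np.exp(-2j * np.pi * np.outer(k, m) / L)
    psds = []
    start = 0
    while start + L <= n:
        seg = x[start:start + L] * w
        p = (np.abs(dftmat @ seg) ** 2) / (fs * np.sum(w ** 2))
        p[1:] *= 2.0
        if L % 2 == 0:
            p[-1] /= 2.0
        psds.append(p)
        start += hop
    psd = np.mean(psds, axis=0)
    freqs = k * fs / L
    out = {}
    for band in bands:
        sel = (freqs >= band.low - 1e-12) & (freqs <= band.high + 1e-12)
        out[band.name] = 10.0 * np.log10(np.mean(psd[sel]))
    return out
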