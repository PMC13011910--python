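"""Real-time alpha feedback engine.

Reproduces the online processing chain of a covert alpha neurofeedback
display: at each feedback update the trailing EEG buffer from the feedback
channel (Pz) is zero-phase bandpass filtered (1-20 Hz, 4th-order
Butterworth), the last 2 s (500 samples at 250 Hz) are Hann-tapered, alpha
(8-12 Hz) spectral power is averaged in dB, and the value is mapped to a
circle radius in pixels.  Consecutive analysis windows overlap by
``window_length - sampling_rate / update_rate`` samples (250 / 450 / 475 at
1 / 5 / 10 Hz updates), and a 3-s preroll lets the first update land on the
trial onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import EEGRecording

#: dB value reported for an all-zero analysis window.
DB_FLOOR = -120.0


@dataclass(frozen=True)
class OnlineConfig:
    bandpass_low: float = 1.0
    bandpass_high: float = 20.0
    filter_order: int = 4
    window_length: int = 500
    band_low: float = 8.0
    band_high: float = 12.0
    update_rate: float = 1.0
    preroll: float = 3.0
    feedback_channel: str = "Pz"
    buffer_cap: float = 10.0            # s of trailing buffer re-filtered

    def __post_init__(self):
        if not self.bandpass_low < self.band_low < self.band_high \
                <= self.bandpass_high:
            raise ValueError("alpha band must lie inside the bandpass")
        if self.update_rate <= 0:
            raise ValueError("update_rate must be positive")


@dataclass(frozen=True)
class RadiusMap:
    """Clamped affine map from alpha power (dB) to circle radius (px)."""

    r_min: float = 50.0
    r_max: float = 200.0
    r_control: float = 100.0
    calibration_low: float = -6.0
    calibration_high: float = 6.0

    def __post_init__(self):
        if not self.r_min < self.r_control < self.r_max:
            raise ValueError("require r_min < r_control < r_max")
        if self.calibration_low >= self.calibration_high:
            raise ValueError("calibration_low must be < calibration_high")


@dataclass
class FeedbackTrace:
    """Per-update feedback sequence for one trial."""

    update_times: np.ndarray            # s relative to trial onset
    alpha_db: np.ndarray
    radius_px: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.update_times)


def compute_overlap(window_length: int, sampling_rate: float,
                    update_rate: float) -> int:
    """Overlap between consecutive analysis windows, in samples.

    ``window_length - sampling_rate / update_rate``; the hop must be a
    positive integer number of samples.
    """
    hop = sampling_rate / update_rate
    if abs(hop - round(hop)) > 1e-9 or round(hop) < 1:
        raise ValueError(
            f"update rate {update_rate} Hz incompatible with sampling rate "
            f"{sampling_rate} Hz (non-integer hop)")
    overlap = window_length - int(round(hop))
    if overlap < 0:
        raise ValueError("update rate too low: windows would not overlap "
                         "a full hop")
    return overlap


def bandpass_zero_phase(x: np.ndarray, low: float, high: float,
                        order: int, fs: float) -> np.ndarray:
    """Forward-backward Butterworth bandpass (zero phase distortion)."""
    if len(x) <= 3 * (2 * order + 1):
        raise ValueError("signal too short for zero-phase filtering")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, x)


def window_alpha_power(window: np.ndarray, sampling_rate: float,
                       band: tuple = (8.0, 12.0)) -> float:
    """Alpha power of one analysis window, in dB re 1 μV²/Hz.

    Single symmetric-Hann-tapered periodogram over the full window; spectral
    estimates at bins with ``band[0] <= f <= band[1]`` (inclusive edges) are
    averaged before the 10*log10 conversion.
    """
    window = np.asarray(window, dtype=float)
    taper = signal.windows.hann(len(window), sym=True)
    freqs, psd = signal.periodogram(
        window, fs=sampling_rate, window=taper, detrend=False,
        scaling="density")
    sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    mean_power = float(np.mean(psd[sel]))
    if mean_power <= 0.0:
        return DB_FLOOR
    return float(10.0 * np.log10(mean_power))


def map_alpha_to_radius(alpha_db: float, rmap: RadiusMap) -> float:
    """Affine alpha->radius map, clamped to [r_min, r_max]; non-decreasing."""
    frac = ((alpha_db - rmap.calibration_low)
            / (rmap.calibration_high - rmap.calibration_low))
    return float(rmap.r_min + (rmap.r_max - rmap.r_min)
                 * min(max(frac, 0.0), 1.0))


def run_feedback_loop(recording: EEGRecording, cfg: OnlineConfig,
                      rmap: RadiusMap) -> FeedbackTrace:
    """Run the online engine over one trial recording.

    The recording must include the preroll.  At each update instant (hop =
    sampling_rate / update_rate, first update at trial onset) the trailing
    buffer (capped at ``buffer_cap`` seconds) is zero-phase filtered and the
    final ``window_length`` processed samples feed the alpha estimator, so
    the emitted radius at update k depends only on samples up to that
    instant.
    """
    fs = recording.sampling_rate
    x = recording.channel(cfg.feedback_channel)
    hop = int(round(fs / cfg.update_rate))
    compute_overlap(cfg.window_length, fs, cfg.update_rate)  # validates hop
    preroll_samples = int(round(cfg.preroll * fs))
    if preroll_samples < cfg.window_length:
        raise ValueError("preroll shorter than one analysis window")
    trial_samples = len(x) - preroll_samples
    if trial_samples <= 0:
        raise ValueError("recording shorter than its preroll")
    n_updates = int(np.floor(trial_samples / fs * cfg.update_rate))
    cap = int(round(cfg.buffer_cap * fs))

    times = np.empty(n_updates)
    alpha = np.empty(n_updates)
    radius = np.empty(n_updates)
    for k in range(n_updates):
        end = preroll_samples + k * hop
        start = max(0, end - cap)
        buf = bandpass_zero_phase(x[start:end], cfg.bandpass_low,
                                  cfg.bandpass_high, cfg.filter_order, fs)
        win = buf[-cfg.window_length:]
        a = window_alpha_power(win, fs, (cfg.band_low, cfg.band_high))
        times[k] = k * hop / fs
        alpha[k] = a
        radius[k] = map_alpha_to_radius(a, rmap)
    return FeedbackTrace(update_times=times, alpha_db=alpha,
                         radius_px=radius,
                         metadata=dict(recording.metadata))


def replay_feedback(trace_library: list, rng,
                    n_updates: int | None = None,
                    rmap: RadiusMap | None = None) -> FeedbackTrace:
    """Sham feedback: replay alpha variations sampled from a trace library.

    Each per-step alpha increment is drawn at random from the pooled
    increments of previously recorded traces, so the emitted radius sequence
    is statistically independent of any concurrent recording (the "offline
    alpha" feedback source).
    """
    if not trace_library:
        raise ValueError("trace library is empty")
    rmap = rmap or RadiusMap()
    ref = trace_library[0]
    if n_updates is None:
        n_updates = len(ref)
    deltas = np.concatenate([np.diff(t.alpha_db) for t in trace_library
                             if len(t) > 1])
    starts = np.array([t.alpha_db[0] for t in trace_library])
    alpha = np.empty(n_updates)
    alpha[0] = rng.choice(starts)
    if deltas.size == 0:
        alpha[1:] = alpha[0]
    else:
        alpha[1:] = alpha[0] + np.cumsum(rng.choice(deltas,
                                                    size=n_updates - 1))
    dt = (ref.update_times[1] - ref.update_times[0]) if len(ref) > 1 else 1.0
    times = np.arange(n_updates) * dt
    radius = np.array([map_alpha_to_radius(a, rmap) for a in alpha])
    return FeedbackTrace(update_times=times, alpha_db=alpha,
                         radius_px=radius, metadata={"source": "offline"})
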