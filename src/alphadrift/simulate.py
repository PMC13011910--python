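"""Synthetic EEG sessions with a known time-on-task alpha drift.

The generator emulates a covert neurofeedback session: six-channel EEG
(Fp1, Fpz, Fp2, Fz, Cz, Pz; left-earlobe reference convention) at 250 Hz,
sixty-second trials organised as four conditions x eight trials, with a
1/f-like broadband background, four band-limited oscillators (theta, alpha,
SMR, beta), eye-blink transients dominating the frontal channels, and a
linear per-trial upward drift of the alpha amplitude with per-subject random
intercepts and slopes.  Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

CHANNELS = ("Fp1", "Fpz", "Fp2", "Fz", "Cz", "Pz")
CONDITIONS = ("Control", "1Hz", "5Hz", "10Hz")

#: The four predefined condition-order quadruplets (1-based condition digits).
QUADRUPLETS = ("1342", "2413", "3124", "4231")

#: Oscillator source bands, Hz.  Each rhythm is generated as a peaked
#: component inset within its classical analysis band (theta 4-8, alpha
#: 8-12, SMR 12-15, beta 15-30 Hz): real rhythms are spectrally peaked
#: (e.g., the individual alpha peak near 10 Hz), and a brick-wall source
#: would park power exactly on the shared analysis-band edges.
OSC_BANDS = {"theta": (4.5, 7.5), "alpha": (9.0, 11.0),
             "smr": (12.5, 14.5), "beta": (16.0, 28.0)}

#: Spatial mixing weights over (Fp1, Fpz, Fp2, Fz, Cz, Pz).  Alpha is
#: posterior-dominant (strongest at Pz), theta frontal-midline, SMR central,
#: blinks frontal.  Rank-1 mixing per source keeps ICA separation feasible
#: at six channels.
TOPOGRAPHIES = {
    "theta": np.array([0.40, 0.50, 0.40, 1.00, 0.80, 0.50]),
    "alpha": np.array([0.20, 0.20, 0.20, 0.40, 0.60, 1.00]),
    "smr":   np.array([0.20, 0.20, 0.20, 0.60, 1.00, 0.50]),
    "beta":  np.array([0.50, 0.50, 0.50, 0.80, 0.80, 0.80]),
    "blink": np.array([1.00, 1.00, 1.00, 0.50, 0.20, 0.05]),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generative settings for one simulated experiment.

    Amplitudes are RMS microvolts of the corresponding source at its
    strongest channel.  ``alpha_trial_slope`` is the population mean of the
    per-subject alpha drift per trial: in ``drift_unit="uv"`` the alpha
    source RMS at trial t is ``intercept + slope * (t - 1)`` (microvolts);
    in ``drift_unit="db"`` it is ``intercept * 10**(slope * (t - 1) / 20)``
    so the alpha band power in dB rises linearly by ``slope`` dB per trial.
    """

    sampling_rate: float = 250.0
    channels: tuple = CHANNELS
    trial_duration: float = 60.0
    preroll: float = 3.0
    n_trials_per_condition: int = 8
    conditions: tuple = CONDITIONS
    background_exponent: float = 1.0
    background_rms: float = 5.0
    band_amplitudes: dict = field(default_factory=lambda: {
        "theta": 2.0, "alpha": 4.0, "smr": 1.5, "beta": 1.5})
    alpha_trial_slope: float = 0.025
    drift_unit: str = "uv"
    subject_sd_intercept: float = 0.8
    subject_sd_slope: float = 0.008
    blink_rate: float = 15.0
    blink_amplitude: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.trial_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration x sampling_rate must be an "
                             "integer sample count")
        if len(self.conditions) != 4:
            raise ValueError("exactly 4 conditions are required")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band_amplitudes must be non-negative")
        if self.drift_unit not in ("uv", "db"):
            raise ValueError("drift_unit must be 'uv' or 'db'")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def samples_per_trial(self) -> int:
        """Samples including the preroll."""
        return int(round((self.preroll + self.trial_duration)
                         * self.sampling_rate))


@dataclass
class EEGRecording:
    """One trial of multi-channel EEG in microvolts.

    ``data`` is channels x samples; ``annotations`` is a list of
    (onset_sample, duration_samples, label) tuples; ``metadata`` carries
    subject / experiment (feedback source) / condition / trial indices.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple
    annotations: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must have one row per channel label")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        n = self.data.shape[1]
        for onset, dur, _ in self.annotations:
            if not (0 <= onset < n):
                raise ValueError("annotation onset outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not present") from err
        return self.data[idx]


@dataclass
class SubjectTruth:
    """Realised per-subject alpha drift parameters."""

    subject: int
    alpha_intercept: float
    alpha_slope: float


@dataclass
class GroundTruth:
    """Per-subject-trial record of what was injected (for recovery tests)."""

    subjects: list = field(default_factory=list)
    trials: list = field(default_factory=list)   # dicts: subject, trial, ...

    def trial_table(self):
        import pandas as pd
        return pd.DataFrame(self.trials)


def assign_condition_order(participant_index: int, seed: int) -> tuple:
    """Condition order for one participant under the partial Latin square.

    Each block of four consecutive participants receives a seeded random
    permutation of the four predefined quadruplets, so over any 4k aligned
    participants every quadruplet occurs exactly k times.
    """
    if participant_index < 0:
        raise ValueError("participant_index must be non-negative")
    block, pos = divmod(participant_index, 4)
    rng = np.random.default_rng([seed, 0xC0DE, block])
    perm = rng.permutation(4)
    quad = QUADRUPLETS[perm[pos]]
    return tuple(CONDITIONS[int(d) - 1] for d in quad)


def _trial_rng(config: SimulationConfig, subject: int, trial_index: int,
               stream: int = 0):
    """Counter-based RNG split: each trial reproducible independently."""
    return np.random.default_rng(
        [config.seed, 0xA1FA, subject, trial_index, stream])


def _pink_noise(rng, n_channels: int, n_samples: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent background, independent per channel, scaled to RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs >= 0.5                      # flatten below 0.5 Hz, kill DC
    shape[nz] = (freqs[nz] / 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x


def _narrowband(rng, n_samples: int, fs: float, low: float,
                high: float) -> np.ndarray:
    """Unit-RMS narrowband noise: bandpass-filtered white noise.

    The exact unit-RMS rescaling makes the injected source variance a
    deterministic function of the configured amplitude.
    """
    sos = signal.butter(3, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / np.sqrt(np.mean(x ** 2))


def alpha_amplitude(config: SimulationConfig, intercept: float,
                    slope: float, trial_index: int) -> float:
    """Alpha source RMS (μV) for session trial ``trial_index`` (1-based)."""
    if config.drift_unit == "uv":
        return max(intercept + slope * (trial_index - 1), 0.0)
    return intercept * 10.0 ** (slope * (trial_index - 1) / 20.0)


def generate_trial(config: SimulationConfig, subject_truth: SubjectTruth,
                   trial_index: int, condition: str = "Control",
                   source_label: str = "online") -> EEGRecording:
    """Generate one preroll+trial recording for one subject.

    The alpha source amplitude follows the subject's realised intercept and
    slope at ``trial_index`` (1-based session trial, 1..32); the other bands
    are stationary.  Blinks are injected afterwards via :func:`inject_blinks`
    when ``config.blink_rate > 0``.
    """
    if not 1 <= trial_index <= 32:
        raise ValueError("trial_index must be in [1, 32]")
    fs = config.sampling_rate
    n = config.samples_per_trial
    rng = _trial_rng(config, subject_truth.subject, trial_index)

    data = _pink_noise(rng, config.n_channels, n, fs,
                       config.background_exponent, config.background_rms)

    for band, (lo, hi) in OSC_BANDS.items():
        amp = config.band_amplitudes.get(band, 0.0)
        if band == "alpha":
            amp = alpha_amplitude(config, subject_truth.alpha_intercept,
                                  subject_truth.alpha_slope, trial_index)
        if amp <= 0:
            continue
        src = _narrowband(rng, n, fs, lo, hi)
        weights = TOPOGRAPHIES[band][:config.n_channels]
        data += amp * np.outer(weights, src)

    rec = EEGRecording(
        data=data, sampling_rate=fs, channel_labels=tuple(config.channels),
        annotations=[(int(round(config.preroll * fs)),
                      int(round(config.trial_duration * fs)), "trial")],
        metadata={"subject": subject_truth.subject, "trial": trial_index,
                  "condition": condition, "source": source_label,
                  "preroll": config.preroll},
    )
    if config.blink_rate > 0:
        rec = inject_blinks(rec, config.blink_rate, config.blink_amplitude,
                            _trial_rng(config, subject_truth.subject,
                                       trial_index, stream=1))
    return rec


def inject_blinks(recording: EEGRecording, rate: float, amplitude: float,
                  rng) -> EEGRecording:
    """Add stereotyped eye-blink transients with a frontal topography.

    Blinks are raised-cosine transients of 100-400 ms drawn from a Poisson
    process at ``rate`` events/min; each event is annotated.  ``rate == 0``
    returns the input unchanged.
    """
    if rate < 0:
        raise ValueError("blink rate must be non-negative")
    if rate == 0:
        return recording
    fs = recording.sampling_rate
    n = recording.n_samples
    duration_s = n / fs
    n_events = rng.poisson(rate * duration_s / 60.0)
    data = recording.data.copy()
    annotations = list(recording.annotations)
    weights = TOPOGRAPHIES["blink"][:data.shape[0]]
    for _ in range(n_events):
        width = int(rng.uniform(0.100, 0.400) * fs)
        onset = int(rng.uniform(0, n - width))
        pulse = amplitude * 0.5 * (1 - np.cos(
            2 * np.pi * np.arange(width) / width))
        data[:, onset:onset + width] += np.outer(weights, pulse)
        annotations.append((onset, width, "blink"))
    return EEGRecording(data=data, sampling_rate=fs,
                        channel_labels=recording.channel_labels,
                        annotations=annotations,
                        metadata=dict(recording.metadata))


def draw_subject_truth(config: SimulationConfig, subject: int) -> SubjectTruth:
    rng = np.random.default_rng([config.seed, 0x5B1, subject])
    base = (config.band_amplitudes["alpha"]
            + config.subject_sd_intercept * rng.standard_normal())
    slope = (config.alpha_trial_slope
             + config.subject_sd_slope * rng.standard_normal())
    return SubjectTruth(subject=subject,
                        alpha_intercept=max(base, 0.25),
                        alpha_slope=slope)


def generate_experiment(config: SimulationConfig, n_subjects: int,
                        source_label: str = "online", seed: int | None = None):
    """Generate a full experiment: n_subjects x 32 trials plus ground truth.

    ``source_label`` ("online" / "offline") is recorded in metadata only: the
    feedback source manipulates the display path, not the EEG generator, so
    the generated signals are statistically identical across source arms.
    Returns ``(recordings, ground_truth)`` with recordings in session order.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is not None:
        config = replace(config, seed=seed)
    truth = GroundTruth()
    recordings = []
    n_cond = len(config.conditions)
    for subj in range(n_subjects):
        st = draw_subject_truth(config, subj)
        truth.subjects.append(st)
        order = assign_condition_order(subj, config.seed)
        session_trial = 0
        for cond in order:
            for _ in range(config.n_trials_per_condition):
                session_trial += 1
                rec = generate_trial(config, st, session_trial,
                                     condition=cond,
                                     source_label=source_label)
                within = ((session_trial - 1)
                          % config.n_trials_per_condition) + 1
                rec.metadata["trial_in_condition"] = within
                recordings.append(rec)
                truth.trials.append({
                    "subject": subj, "source": source_label,
                    "condition": cond, "trial": session_trial,
                    "trial_in_condition": within,
                    "alpha_amplitude": alpha_amplitude(
                        config, st.alpha_intercept, st.alpha_slope,
                        session_trial),
                    "alpha_intercept": st.alpha_intercept,
                    "alpha_slope": st.alpha_slope,
                    "n_blinks": sum(1 for a in rec.annotations
                                    if a[2] == "blink"),
                })
        assert session_trial == n_cond * config.n_trials_per_condition
    return recordings, truth
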