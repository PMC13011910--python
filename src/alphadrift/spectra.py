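"""Offline preprocessing and band-power extraction.

Pipeline: zero-phase 0.5 Hz high-pass (6th-order Butterworth) and 50 Hz
notch (2nd-order IIR) per channel and trial; extended-Infomax ICA with an
automated ocular-component rejection rule; Welch band powers (up to eight
50%-overlapping Hamming-tapered segments) in dB for theta (4-8), alpha
(8-12), SMR (12-15) and beta (15-30 Hz) at Fz, Cz and Pz; z-scoring of each
band x channel variable across the subject-trials of each experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import EEGRecording

ANALYSIS_CHANNELS = ("Fz", "Cz", "Pz")


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("band low must be < high")


#: The four classical neurofeedback target bands.  Edge bins (8, 12, 15 Hz)
#: are counted in both adjacent bands (inclusive-edge convention).
BANDS = (Band("theta", 4.0, 8.0), Band("alpha", 8.0, 12.0),
         Band("smr", 12.0, 15.0), Band("beta", 15.0, 30.0))


@dataclass
class ICAReport:
    n_components_removed: int
    rejection_scores: list          # per-component dicts
    mixing: np.ndarray | None = None
    unmixing: np.ndarray | None = None


def preprocess(recording: EEGRecording, highpass: float = 0.5,
               hp_order: int = 6, notch: float = 50.0,
               notch_q: float = 35.0) -> EEGRecording:
    """Zero-phase high-pass then notch filtering, per channel.

    The notch is a 2nd-order IIR (biquad) applied forward-backward.
    """
    fs = recording.sampling_rate
    if recording.n_samples < 10 * fs:
        raise ValueError("recording shorter than 10 s")
    sos_hp = signal.butter(hp_order, highpass, btype="highpass", fs=fs,
                           output="sos")
    b, a = signal.iirnotch(notch, notch_q, fs=fs)
    data = signal.sosfiltfilt(sos_hp, recording.data, axis=1)
    data = signal.filtfilt(b, a, data, axis=1)
    return EEGRecording(data=data, sampling_rate=fs,
                        channel_labels=recording.channel_labels,
                        annotations=list(recording.annotations),
                        metadata=dict(recording.metadata))


def remove_ocular_components(session: list, rng=None,
                             corr_threshold: float = 0.7,
                             lowfreq_threshold: float = 0.6,
                             max_remove: int = 3,
                             max_fit_samples: int = 12000,
                             max_iter: int = 60):
    """Extended-Infomax ICA cleanup of a subject's session.

    ICA is fit on the concatenated (preprocessed) trials.  A component is
    rejected as ocular when its time series correlates with the mean of the
    frontopolar (Fp*) channels above ``corr_threshold`` in magnitude AND
    more than ``lowfreq_threshold`` of its power lies below 4 Hz — the
    signature of eye blinks.  Rejected components (at most ``max_remove``)
    are zeroed and the data back-projected.  Returns (cleaned session,
    :class:`ICAReport`).

    For long sessions the unmixing matrix is fit on an evenly strided
    subsample of at most ``max_fit_samples`` samples (Infomax treats
    samples as exchangeable, so striding is unbiased) and applied to the
    full data.  ``max_iter`` bounds the annealing: at six channels the
    ocular separation is stable well before 60 passes, while the default
    annealing schedule can oscillate for hundreds.
    """
    from mne.preprocessing import infomax

    if not session:
        raise ValueError("empty session")
    labels = session[0].channel_labels
    if len(labels) < 2:
        raise ValueError("ICA requires at least 2 channels")
    fs = session[0].sampling_rate
    concat = np.concatenate([r.data for r in session], axis=1)
    if concat.shape[1] < 20 * concat.shape[0] ** 2:
        raise ValueError("session too short for a stable ICA decomposition")

    seed = 0 if rng is None else int(rng.integers(2 ** 31 - 1))
    # PCA-whiten before Infomax (as EEGLAB/MNE do): Infomax converges to
    # the rotation on sphered data.
    mean = concat.mean(axis=1, keepdims=True)
    centered = concat - mean
    evals, evecs = np.linalg.eigh(np.cov(centered))
    sphere = (evecs / np.sqrt(evals)) @ evecs.T
    stride = max(1, int(np.ceil(centered.shape[1] / max_fit_samples)))
    white_fit = sphere @ centered[:, ::stride]
    # w_change 1e-7 is the conventional weight-change stopping tolerance
    # for <33-channel decompositions; far tighter values only prolong the
    # annealing without changing the unmixing.
    w_rot = infomax(white_fit.T, extended=True, rng=seed, verbose="error",
                    w_change=1e-7, max_iter=max_iter)
    unmixing = w_rot @ sphere
    mixing = np.linalg.pinv(unmixing)
    sources = unmixing @ centered

    fp_idx = [i for i, l in enumerate(labels) if l.startswith("Fp")]
    fp_mean = concat[fp_idx].mean(axis=0) if fp_idx else concat.mean(axis=0)

    scores, rejected = [], []
    for k in range(sources.shape[0]):
        src = sources[k]
        corr = float(np.corrcoef(src, fp_mean)[0, 1])
        freqs, psd = signal.welch(src, fs=fs,
                                  nperseg=min(len(src), 4096))
        lowfrac = float(psd[freqs < 4.0].sum() / psd.sum())
        is_ocular = abs(corr) > corr_threshold and lowfrac > lowfreq_threshold
        scores.append({"component": k, "fp_corr": corr,
                       "lowfreq_fraction": lowfrac, "rejected": is_ocular})
        if is_ocular:
            rejected.append(k)
    # strongest frontal correlation first if more than max_remove qualify
    rejected = sorted(rejected,
                      key=lambda k: -abs(scores[k]["fp_corr"]))[:max_remove]
    for s in scores:
        s["rejected"] = s["component"] in rejected

    keep = np.ones(sources.shape[0], dtype=bool)
    keep[rejected] = False
    cleaned_concat = mixing[:, keep] @ sources[keep] + mean

    cleaned, pos = [], 0
    for rec in session:
        n = rec.n_samples
        cleaned.append(EEGRecording(
            data=cleaned_concat[:, pos:pos + n].copy(),
            sampling_rate=fs, channel_labels=labels,
            annotations=list(rec.annotations),
            metadata=dict(rec.metadata)))
        pos += n
    report = ICAReport(n_components_removed=len(rejected),
                       rejection_scores=scores, mixing=mixing,
                       unmixing=unmixing)
    return cleaned, report


def welch_segment_length(n_samples: int) -> int:
    """Segment length so that eight 50%-overlapping segments tile the trial."""
    return int(np.floor(2 * n_samples / 9))


def welch_band_power(x: np.ndarray, sampling_rate: float,
                     bands: tuple = BANDS) -> dict:
    """Welch band powers of one trial signal, in dB re 1 μV²/Hz.

    Hamming-tapered periodograms over eight 50%-overlapping segments are
    averaged; each band's power is the mean spectral estimate over bins with
    ``low <= f <= high`` (inclusive edges), converted to 10*log10.
    """
    x = np.asarray(x, dtype=float)
    nperseg = welch_segment_length(len(x))
    if nperseg < 2:
        raise ValueError("signal shorter than one Welch segment")
    taper = signal.windows.hamming(nperseg, sym=True)
    freqs, psd = signal.welch(x, fs=sampling_rate, window=taper,
                              nperseg=nperseg, noverlap=nperseg // 2,
                              detrend=False, scaling="density")
    out = {}
    for band in bands:
        sel = (freqs >= band.low - 1e-12) & (freqs <= band.high + 1e-12)
        out[band.name] = float(10.0 * np.log10(np.mean(psd[sel])))
    return out


def band_power_table(recordings: list, channels: tuple = ANALYSIS_CHANNELS,
                     bands: tuple = BANDS, exclude_preroll: bool = True
                     ) -> pd.DataFrame:
    """Long-format band-power table over trials x channels x bands.

    Preroll samples are excluded from the offline spectra (trial onset to
    offset only).  Columns: source, subject, condition, trial,
    trial_in_condition, channel, band, power_db.
    """
    rows = []
    for rec in recordings:
        md = rec.metadata
        start = 0
        if exclude_preroll:
            start = int(round(md.get("preroll", 0.0) * rec.sampling_rate))
        for ch in channels:
            powers = welch_band_power(rec.channel(ch)[start:],
                                      rec.sampling_rate, bands)
            for band, db in powers.items():
                rows.append({
                    "source": md.get("source", "online"),
                    "subject": md.get("subject", 0),
                    "condition": md.get("condition", "Control"),
                    "trial": md.get("trial", 1),
                    "trial_in_condition": md.get("trial_in_condition",
                                                 md.get("trial", 1)),
                    "channel": ch, "band": band, "power_db": db,
                })
    return pd.DataFrame(rows)


def zscore_standardize(table: pd.DataFrame,
                       grouping: str = "source") -> pd.DataFrame:
    """Z-score each band x channel variable across subject-trials, within
    each experiment (feedback source) separately.

    Adds a ``power_z`` column; raises on zero-variance cells.
    """
    table = table.copy()
    grp = table.groupby([grouping, "channel", "band"], sort=False)["power_db"]
    sd = grp.transform("std", ddof=0)
    if (sd <= 0).any() or sd.isna().any():
        raise ValueError("zero-variance cell in band-power table")
    table["power_z"] = (table["power_db"] - grp.transform("mean")) / sd
    return table
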