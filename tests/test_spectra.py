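"""Offline pipeline: filters, Welch band power vs brute-force oracle, ICA
ocular cleanup, table construction and z-scoring."""

import numpy as np
import pandas as pd
import pytest

from alphadrift import (BANDS, SimulationConfig, band_power_table,
                        draw_subject_truth, generate_trial, inject_blinks,
                        preprocess, remove_ocular_components,
                        welch_band_power, welch_segment_length,
                        zscore_standardize)


class TestPreprocess:
    def test_dc_removed(self, short_trial):
        rec = short_trial
        rec.data[0] += 100.0
        out = preprocess(rec)
        assert abs(out.data[0].mean()) < 0.5

    def test_mains_notch(self):
        from alphadrift.simulate import EEGRecording
        fs = 250.0
        t = np.arange(int(12 * fs)) / fs
        x = np.tile(np.sin(2 * np.pi * 50.0 * t), (6, 1))
        rec = EEGRecording(data=x, sampling_rate=fs,
                          channel_labels=("Fp1", "Fpz", "Fp2", "Fz", "Cz",
                                          "Pz"))
        out = preprocess(rec)
        core = slice(int(2 * fs), int(10 * fs))
        assert (np.sqrt(np.mean(out.data[0, core] ** 2))
                < 0.1 * np.sqrt(np.mean(x[0, core] ** 2)))

    def test_passband_preserved(self):
        from alphadrift.simulate import EEGRecording
        fs = 250.0
        t = np.arange(int(12 * fs)) / fs
        x = np.tile(np.sin(2 * np.pi * 10.0 * t), (6, 1))
        rec = EEGRecording(data=x, sampling_rate=fs,
                          channel_labels=("Fp1", "Fpz", "Fp2", "Fz", "Cz",
                                          "Pz"))
        out = preprocess(rec)
        core = slice(int(2 * fs), int(10 * fs))
        gain = (np.sqrt(np.mean(out.data[0, core] ** 2))
                / np.sqrt(np.mean(x[0, core] ** 2)))
        assert gain == pytest.approx(1.0, abs=0.02)

    def test_short_recording_rejected(self, short_config):
        from alphadrift.simulate import EEGRecording
        rec = EEGRecording(data=np.zeros((6, 500)), sampling_rate=250.0,
                          channel_labels=("Fp1", "Fpz", "Fp2", "Fz", "Cz",
                                          "Pz"))
        with pytest.raises(ValueError):
            preprocess(rec)

    def test_near_idempotent_in_band(self, short_trial):
        """Filtering twice moves 4-30 Hz band powers by < 0.2 dB."""
        once = preprocess(short_trial)
        twice = preprocess(once)
        for ch in ("Fz", "Pz"):
            a = welch_band_power(once.channel(ch), 250.0)
            b = welch_band_power(twice.channel(ch), 250.0)
            for band in a:
                assert abs(a[band] - b[band]) < 0.2


class TestWelch:
    def test_segment_length_rule(self):
        assert welch_segment_length(15000) == 3333
        assert welch_segment_length(2500) == 555

    def test_matches_brute_force_oracle(self, rng):
        from conftest import welch_hamming_oracle
        for _ in range(5):
            x = rng.standard_normal(1000)
            got = welch_band_power(x, 250.0)
            want = welch_hamming_oracle(x, 250.0, BANDS)
            for band in got:
                assert abs(got[band] - want[band]) < 1e-9

    def test_sinusoid_lands_in_its_band(self):
        t = np.arange(2500) / 250.0
        p = welch_band_power(np.sin(2 * np.pi * 10.0 * t), 250.0)
        for other in ("theta", "smr", "beta"):
            assert p["alpha"] - p[other] > 20.0

    def test_white_noise_is_flat(self, rng):
        """Beta minus alpha band power ~ 0 dB for white noise."""
        diffs = []
        for _ in range(40):
            x = rng.standard_normal(5000)
            p = welch_band_power(x, 250.0)
            diffs.append(p["beta"] - p["alpha"])
        assert abs(np.mean(diffs)) < 0.5

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            welch_band_power(np.zeros(5), 250.0)


@pytest.fixture(scope="module")
def blink_session():
    """One subject, 8 preprocessed 10-s trials with strong blinks."""
    cfg = SimulationConfig(trial_duration=10.0, blink_rate=25.0,
                           blink_amplitude=150.0, seed=77)
    st = draw_subject_truth(cfg, 0)
    return [preprocess(generate_trial(cfg, st, t)) for t in range(1, 9)]


@pytest.fixture(scope="module")
def clean_session():
    cfg = SimulationConfig(trial_duration=10.0, blink_rate=0.0, seed=78)
    st = draw_subject_truth(cfg, 0)
    return [preprocess(generate_trial(cfg, st, t)) for t in range(1, 9)]


class TestICA:
    def test_blink_components_removed(self, blink_session):
        rng = np.random.default_rng(1)
        cleaned, report = remove_ocular_components(blink_session, rng)
        assert 1 <= report.n_components_removed <= 3
        before = np.var(np.concatenate(
            [r.channel("Fp1") for r in blink_session]))
        after = np.var(np.concatenate(
            [r.channel("Fp1") for r in cleaned]))
        assert after < 0.5 * before

    def test_blink_free_data_untouched(self, clean_session):
        rng = np.random.default_rng(2)
        cleaned, report = remove_ocular_components(clean_session, rng)
        assert report.n_components_removed == 0
        for a, b in zip(clean_session, cleaned):
            pa = welch_band_power(a.channel("Pz"), 250.0)["alpha"]
            pb = welch_band_power(b.channel("Pz"), 250.0)["alpha"]
            assert abs(pa - pb) < 0.1

    def test_alpha_preserved_after_blink_removal(self, blink_session):
        """Cleanup targets frontal low-frequency activity, not the
        posterior alpha rhythm."""
        rng = np.random.default_rng(3)
        cleaned, _ = remove_ocular_components(blink_session, rng)
        pa = np.mean([welch_band_power(r.channel("Pz"), 250.0)["alpha"]
                      for r in blink_session])
        pb = np.mean([welch_band_power(r.channel("Pz"), 250.0)["alpha"]
                      for r in cleaned])
        assert abs(pa - pb) < 1.5

    def test_too_short_session_rejected(self, clean_session):
        short = [clean_session[0]]
        short[0].data = short[0].data[:, :500]
        with pytest.raises(ValueError):
            remove_ocular_components(short, np.random.default_rng(0))


class TestBandPowerTable:
    def test_schema_and_counts(self, short_config):
        from alphadrift import generate_experiment
        recs, _ = generate_experiment(short_config, 2)
        table = band_power_table(recs[:8])
        # 8 trials x 3 channels x 4 bands
        assert len(table) == 8 * 3 * 4
        assert set(table["channel"]) == {"Fz", "Cz", "Pz"}
        assert set(table["band"]) == {"theta", "alpha", "smr", "beta"}

    def test_preroll_exclusion_changes_nothing_structural(self,
                                                          short_config):
        from alphadrift import generate_experiment
        recs, _ = generate_experiment(short_config, 1)
        with_pre = band_power_table(recs[:2], exclude_preroll=False)
        without = band_power_table(recs[:2], exclude_preroll=True)
        assert not np.allclose(with_pre["power_db"], without["power_db"])


class TestZScore:
    def _table(self, rng, offset=0.0, scale=1.0, source="online"):
        rows = []
        for subj in range(4):
            for trial in range(1, 9):
                for ch in ("Fz", "Cz", "Pz"):
                    for band in ("theta", "alpha", "smr", "beta"):
                        rows.append({"source": source, "subject": subj,
                                     "condition": "Control", "trial": trial,
                                     "trial_in_condition": trial,
                                     "channel": ch, "band": band,
                                     "power_db": offset + scale
                                     * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_unit_moments_per_cell(self, rng):
        z = zscore_standardize(self._table(rng))
        g = z.groupby(["source", "channel", "band"])["power_z"]
        assert np.allclose(g.mean(), 0.0, atol=1e-9)
        assert np.allclose(g.std(ddof=0), 1.0, atol=1e-9)

    def test_affine_invariance(self, rng):
        t = self._table(rng)
        t2 = t.copy()
        t2["power_db"] = 3.0 * t2["power_db"] - 7.0
        z1 = zscore_standardize(t)["power_z"]
        z2 = zscore_standardize(t2)["power_z"]
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_experiments_standardized_independently(self, rng):
        a = self._table(rng, offset=0.0, source="online")
        b = self._table(rng, offset=25.0, source="offline")
        z = zscore_standardize(pd.concat([a, b], ignore_index=True))
        for src in ("online", "offline"):
            g = z[z["source"] == src].groupby(["channel",
                                               "band"])["power_z"]
            assert np.allclose(g.mean(), 0.0, atol=1e-9)

    def test_zero_variance_cell_rejected(self, rng):
        t = self._table(rng)
        t.loc[(t["channel"] == "Pz") & (t["band"] == "alpha"),
              "power_db"] = 5.0
        with pytest.raises(ValueError):
            zscore_standardize(t)


def test_band_partition_inclusive_edges():
    """Every bin in 4-30 Hz belongs to at least one band; edges to both."""
    freqs = np.arange(4.0, 30.0001, 0.25)
    for f in freqs:
        n = sum(1 for b in BANDS if b.low <= f <= b.high)
        assert n >= 1
        if f in (8.0, 12.0, 15.0):
            assert n == 2
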