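"""ERP pipeline: filters, line noise, referencing, epoching, rejection, N1."""

import numpy as np
import pandas as pd
import pytest

from cheechlab import erp, simulate
from cheechlab.erp import (
    EEGRecording,
    apply_filters,
    detect_line_noise,
    epoch_and_baseline,
    extract_n1,
    filter_response_db,
    reject_epochs,
    remove_line_noise,
    rereference,
)
from cheechlab.simulate import EvokedKernel, NoiseConfig, simulate_eeg


def make_recording(data, fs=512.0, channels=None):
    channels = channels or [f"ch{i}" for i in range(np.atleast_2d(data).shape[0])]
    return EEGRecording(channels, fs, data)


class TestFilters:
    def test_dc_offset_removed_by_initial_hp(self):
        rec = make_recording(np.full((2, 5120), 50.0))
        out = apply_filters(rec, "initial_hp")
        assert np.max(np.abs(out.samples)) < 50.0 * 10 ** (-40 / 20)

    @pytest.mark.parametrize("freq,stage", [(60.0, "final_bp"), (10.0, "final_bp")])
    def test_sinusoid_attenuation_matches_transfer_oracle(self, freq, stage):
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        out = apply_filters(make_recording(x[None, :], fs), stage)
        # measure steady-state amplitude away from the edges
        mid = slice(int(5 * fs), int(15 * fs))
        measured = np.sqrt(2 * np.mean(out.samples[0, mid] ** 2))
        expected_db = filter_response_db(stage, freq, fs)
        measured_db = 20 * np.log10(max(measured, 1e-12))
        assert measured_db == pytest.approx(expected_db, abs=0.5)

    def test_passband_gain_within_half_db(self):
        assert abs(filter_response_db("final_bp", 10.0, 512.0)) < 0.5

    def test_downsample_preserves_slow_content(self):
        fs = 2048.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 7.0 * t)
        out = apply_filters(make_recording(x[None, :], fs), "downsample_512")
        assert out.rate_hz == 512.0
        t2 = np.arange(out.n_samples) / 512.0
        mid = slice(256, -256)
        assert np.max(np.abs(out.samples[0, mid] - np.sin(2 * np.pi * 7.0 * t2)[mid])) < 0.01

    def test_low_rate_rejected_for_bandpass(self):
        rec = make_recording(np.zeros((1, 100)), fs=64.0)
        with pytest.raises(ValueError, match="below twice"):
            apply_filters(rec, "final_bp")

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            apply_filters(make_recording(np.zeros((1, 100))), "magic")


class TestLineNoise:
    def _noise_recording(self, n_channels, seed, line_uv=0.0, line_hz=60.0, fs=512.0, dur=8.0):
        rng = np.random.default_rng(seed)
        n = int(dur * fs)
        data = simulate._one_over_f_noise(rng, n_channels, n, fs, 1.0, 10.0)
        if line_uv:
            t = np.arange(n) / fs
            data[0] += line_uv * np.sin(2 * np.pi * line_hz * t)
        return make_recording(data, fs)

    def test_false_positive_rate_below_one_percent(self):
        # 1,000 pure-1/f channels in blocks
        flagged = 0
        for seed in range(10):
            rep = detect_line_noise(self._noise_recording(100, seed))
            flagged += len(rep.flagged_channels)
        assert flagged / 1000 < 0.01

    @pytest.mark.parametrize("line_hz", [60.0, 120.0])
    def test_injected_line_and_harmonic_flagged(self, line_hz):
        rec = self._noise_recording(4, 1, line_uv=15.0, line_hz=line_hz)
        rep = detect_line_noise(rec)
        assert rep.flagged_channels == ["ch0"]
        assert line_hz in rep.offending_freqs["ch0"]

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_line_noise(make_recording(np.zeros((1, 256)), fs=512.0))

    def test_clean_channels_pass_through_bit_identical(self):
        rec = self._noise_recording(4, 2, line_uv=15.0)
        before = rec.samples.copy()
        cleaned, rep = remove_line_noise(rec)
        assert rep.clean
        np.testing.assert_array_equal(cleaned.samples[1:], before[1:])

    def test_cleaning_brings_corrected_power_below_criterion(self):
        rec = self._noise_recording(4, 3, line_uv=15.0)
        cleaned, rep = remove_line_noise(rec)
        assert rep.clean
        assert rep.iterations_used <= 5
        assert not detect_line_noise(cleaned).flagged_channels

    def test_non_line_spectrum_preserved_within_five_percent(self):
        from scipy.signal import welch

        rec = self._noise_recording(2, 4, line_uv=15.0)
        before = rec.samples[0].copy()
        cleaned, _ = remove_line_noise(rec)
        f, p0 = welch(before, fs=512.0, nperseg=512)
        f, p1 = welch(cleaned.samples[0], fs=512.0, nperseg=512)
        keep = (f > 2) & ~((np.abs(f - 60) < 4) | (np.abs(f - 120) < 4)
                           | (np.abs(f - 180) < 4) | (np.abs(f - 240) < 4))
        assert abs(p1[keep].sum() - p0[keep].sum()) / p0[keep].sum() < 0.05


class TestRereference:
    def test_constant_reference_shifts_all_channels(self):
        data = np.vstack([np.ones(100) * 5, np.zeros(100), np.full(100, 3.0), np.full(100, 3.0)])
        rec = make_recording(data, channels=["Fz", "Cz", "A1", "A2"])
        out = rereference(rec)
        np.testing.assert_allclose(out.channel("Fz"), 5.0 - 3.0)
        np.testing.assert_allclose(out.channel("Cz"), -3.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal((4, 200)), channels=["Fz", "Cz", "A1", "A2"])
        once = rereference(rec)
        twice = rereference(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_mastoid_fallback_and_cz_restoration(self):
        rec = make_recording(np.ones((3, 50)), channels=["Fz", "M1", "M2"])
        out = rereference(rec)
        assert "Cz" in out.channel_names
        assert out.meta["reference"] == ("M1", "M2")
        np.testing.assert_allclose(out.channel("Cz"), -1.0)

    def test_dipole_arithmetic_oracle(self):
        fz, a1, a2 = 2.5, 0.5, -0.3
        rec = make_recording(
            np.vstack([np.full(50, fz), np.full(50, a1), np.full(50, a2)]),
            channels=["Fz", "A1", "A2"],
        )
        out = rereference(rec)
        np.testing.assert_allclose(out.channel("Fz"), fz - (a1 + a2) / 2)

    def test_missing_pairs_rejected(self):
        rec = make_recording(np.zeros((1, 50)), channels=["Fz"])
        with pytest.raises(ValueError, match="earlobe"):
            rereference(rec)


class TestEpoching:
    def test_constant_recording_epochs_are_zero(self):
        rec = make_recording(np.full((2, 5120), 7.0))
        es = epoch_and_baseline(rec, [2.0, 4.0])
        assert np.max(np.abs(es.epochs)) == 0.0

    def test_kernel_only_epoch_equals_kernel_minus_prestim(self, default_kernel):
        rate = 512.0
        rec = simulate_eeg([(2.0, "target")], default_kernel, seed=0, rate_hz=rate)
        es = epoch_and_baseline(rec, [2.0])
        n_pre = int(round(0.050 * rate))
        fz = es.epochs[0, es.channel_names.index("Fz")]
        kernel = default_kernel.amplitude_target * default_kernel.sample(rate)
        expected = np.concatenate([np.zeros(n_pre), kernel])[: len(fz)]
        expected -= expected[:n_pre].mean()
        np.testing.assert_allclose(fz, expected, atol=1e-12)

    def test_edge_event_skipped_and_logged(self):
        rec = make_recording(np.zeros((1, 5120)))
        es = epoch_and_baseline(rec, [0.01, 2.0])
        assert es.n_kept == 1
        assert len(es.rejection_log) == 1
        assert "edge" in es.rejection_log[0][1]


def rejection_oracle(data, vt=300.0, z1=6.0, z2=2.0):
    """Independent reimplementation of the two-step rejection rule."""
    keep1 = [i for i in range(len(data)) if np.abs(data[i]).max() <= vt]
    p2p = np.array([[data[i][c].max() - data[i][c].min() for c in range(data.shape[1])] for i in keep1])
    mu, sd = p2p.mean(axis=0), p2p.std(axis=0)
    kept = []
    for row, i in zip(p2p, keep1):
        z = np.where(sd > 0, (row - mu) / np.where(sd > 0, sd, 1), 0.0)
        if z.max() <= z1 and z.mean() <= z2:
            kept.append(i)
    return kept


class TestRejection:
    def _epochs(self, data, fs=512.0):
        n_tr, n_ch, n_s = data.shape
        return erp.EpochSet(
            condition="target",
            epochs=data,
            channel_names=[f"ch{i}" for i in range(n_ch)],
            rate_hz=fs,
            event_times_s=np.arange(n_tr, dtype=float),
            kept_indices=list(range(n_tr)),
        )

    def test_voltage_spike_rejected_in_step_one(self, rng):
        data = rng.standard_normal((20, 4, 282))
        data[7, 2, 100] = 400.0
        out = reject_epochs(self._epochs(data))
        reasons = dict(out.rejection_log)
        assert 7 in reasons and "300" in reasons[7]

    def test_gaussian_epochs_match_oracle_with_low_rejection(self, rng):
        data = rng.standard_normal((60, 6, 282)) * 10
        out = reject_epochs(self._epochs(data))
        assert out.kept_indices == rejection_oracle(data)
        assert out.n_rejected / out.n_total < 0.10

    def test_identical_epochs_not_rejected_in_step_two(self):
        data = np.tile(np.sin(np.linspace(0, 6, 282)), (10, 3, 1))
        out = reject_epochs(self._epochs(data))
        assert out.n_rejected == 0

    def test_epoch_count_conserved(self, rng):
        data = rng.standard_normal((40, 5, 282)) * 50
        data[3] *= 20
        out = reject_epochs(self._epochs(data))
        assert out.n_kept + out.n_rejected == 40


class TestExtractN1:
    def _flat_epochs(self, value, condition, n=4):
        data = np.full((n, 2, 282), float(value))
        es = erp.EpochSet(
            condition=condition,
            epochs=data,
            channel_names=["Fz", "Cz"],
            rate_hz=512.0,
            event_times_s=np.arange(n, dtype=float),
            kept_indices=list(range(n)),
        )
        return es

    def test_flat_averages_give_difference(self):
        res = extract_n1(
            [self._flat_epochs(-1.0, "target"), self._flat_epochs(1.0, "masker")]
        )
        assert res.measures["target"].mean_amplitude_uv == -1.0
        assert res.measures["masker"].mean_amplitude_uv == 1.0
        assert res.difference_uv == -2.0

    def test_window_mean_equals_direct_sum_oracle(self, rng):
        data = rng.standard_normal((6, 2, 282))
        es = erp.EpochSet(
            condition="target",
            epochs=data,
            channel_names=["Fz", "Cz"],
            rate_hz=512.0,
            event_times_s=np.arange(6, dtype=float),
            kept_indices=list(range(6)),
        )
        res = extract_n1([es])
        n_pre = int(round(0.050 * 512))
        lat = (np.arange(282) - n_pre) / 512.0
        idx = [i for i, t in enumerate(lat) if 0.110 <= t < 0.160]
        oracle = data.mean(axis=0)[0, idx].sum() / len(idx)
        assert res.measures["target"].mean_amplitude_uv == pytest.approx(oracle, abs=1e-12)

    def test_missing_fz_rejected(self):
        es = self._flat_epochs(0.0, "target")
        es.channel_names = ["F3", "Cz"]
        with pytest.raises(ValueError, match="Fz"):
            extract_n1([es])


class TestEndToEnd:
    def test_noise_free_pipeline_recovers_configured_difference_exactly(
        self, alternating_events
    ):
        rate = 2048.0
        kernel = EvokedKernel().with_window_means(rate, -0.142, 0.113)
        rec = simulate_eeg(alternating_events, kernel, seed=0, rate_hz=rate)
        rec = rereference(rec)
        sets = []
        for cond in ("target", "masker"):
            times = [t for t, c in alternating_events if c == cond]
            sets.append(epoch_and_baseline(rec, times, cond))
        res = extract_n1(sets)
        assert res.difference_uv == pytest.approx(-0.255, abs=1e-9)

    def test_extracted_differences_track_truth_with_unit_slope(self):
        """Across simulated participants, measured N1 differences regress on
        the generating truth with slope 1 (moderate-noise regime)."""
        from cheechlab.config import ErpConfig, PipelineConfig
        from cheechlab.pipeline import simulate_participant_n1

        cfg = PipelineConfig(
            erp=ErpConfig(
                simulation_rate_hz=1024.0,
                background_rms_uv=0.5,
                epochs_per_condition=60,
            )
        )
        rng = np.random.default_rng(0)
        true = -0.254 + 0.34 * rng.standard_normal(40)
        measured = []
        for i, tv in enumerate(true):
            res = simulate_participant_n1(tv, cfg, seed=1000 + i)
            measured.append(res.difference_uv)
        slope = np.polyfit(true, measured, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)
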