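"""Feature-extraction oracles: sub-epoch grids, multitaper PSDs, band
fractions, closed-form time-domain features, and pipeline invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnoscore.core import ChannelSignal, ConfigurationError, DegenerateSignalError, PolysomnogramRecord
from somnoscore import features as F
from somnoscore.psg_io import MONTAGE_LABELS

FS = 200.0


def _sine(freq, dur_s=2.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestSubEpochs:
    def test_default_30s_epoch_gives_29_windows(self):
        wins = F.segment_subepochs(np.zeros(int(30 * FS)), FS)
        assert wins.shape == (29, int(2 * FS))

    @pytest.mark.parametrize("step_s,expected", [(1.0, 29), (2.0, 15)])
    def test_window_count_formula(self, step_s, expected):
        spec = F.SubEpochSpec(2.0, step_s)
        assert F.segment_subepochs(np.zeros(int(30 * FS)), FS, spec).shape[0] == expected
        assert spec.count(30.0) == expected

    def test_epoch_equal_to_window_gives_one(self):
        assert F.segment_subepochs(np.zeros(int(2 * FS)), FS).shape[0] == 1

    def test_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            F.segment_subepochs(np.zeros(100), FS)

    def test_windows_start_at_step_multiples(self):
        x = np.arange(int(30 * FS), dtype=float)
        wins = F.segment_subepochs(x, FS)
        np.testing.assert_array_equal(wins[:, 0], np.arange(29) * FS)


class TestMultitaperPsd:
    def test_integrated_psd_matches_variance_for_white_noise(self):
        # Parseval check, Monte-Carlo over many draws
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(150):
            x = rng.standard_normal(int(2 * FS))
            freqs, psd = F.multitaper_psd(x - x.mean(), FS)
            df = freqs[1] - freqs[0]
            ratios.append(psd.sum() * df / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_sinusoid_peak_at_its_frequency(self):
        freqs, psd = F.multitaper_psd(_sine(10.0), FS)
        assert abs(freqs[np.argmax(psd)] - 10.0) <= 1.0
        # periodogram oracle agrees on the peak location
        from scipy.signal import periodogram

        f2, p2 = periodogram(_sine(10.0), FS)
        assert abs(f2[np.argmax(p2)] - freqs[np.argmax(psd)]) <= 1.0

    def test_zero_signal_gives_zero_psd(self):
        _, psd = F.multitaper_psd(np.zeros(int(2 * FS)), FS)
        assert np.all(psd == 0.0)

    def test_psd_nonnegative(self):
        rng = np.random.default_rng(1)
        _, psd = F.multitaper_psd(rng.standard_normal(400), FS)
        assert (psd >= 0).all()

    def test_taper_count_limited_by_bandwidth(self):
        with pytest.raises(ValueError):
            F.multitaper_psd(np.zeros(400), FS, nw=2.0, k=5)


class TestBandFractions:
    @pytest.mark.parametrize(
        "freq,band", [(2.0, "delta"), (5.0, "theta"), (10.0, "alpha"), (20.0, "beta")]
    )
    def test_band_pure_sinusoid_lands_in_its_band(self, freq, band):
        freqs, psd = F.multitaper_psd(_sine(freq, dur_s=2.0), FS)
        fr = F.band_power_fractions(freqs, psd)
        assert fr[band] > 0.9
        assert all(v < 0.05 for k, v in fr.items() if k != band)

    def test_fractions_sum_at_most_one(self):
        rng = np.random.default_rng(5)
        freqs, psd = F.multitaper_psd(rng.standard_normal(400), FS)
        fr = F.band_power_fractions(freqs, psd)
        assert all(v >= 0 for v in fr.values())
        assert sum(fr.values()) <= 1.0 + 1e-9

    def test_zero_total_power_errors(self):
        freqs = np.linspace(0, 100, 201)
        with pytest.raises(DegenerateSignalError):
            F.band_power_fractions(freqs, np.zeros_like(freqs))


class TestTimeDomainFeatures:
    def test_line_length_closed_forms(self):
        assert F.line_length(np.full(50, 3.7)) == 0.0
        assert F.line_length(np.array([0.0, 1.0, 0.0, 1.0])) == 3.0
        ramp = np.linspace(0.0, 5.0, 101)  # monotone ramp telescopes to its span
        assert F.line_length(ramp) == pytest.approx(5.0)

    def test_line_length_scales_linearly_with_amplitude(self):
        x = np.random.default_rng(0).standard_normal(400)
        assert F.line_length(7.5 * x) == pytest.approx(7.5 * F.line_length(x))

    def test_kurtosis_of_alternating_signs_is_one(self):
        x = np.tile([1.0, -1.0], 100)
        assert F.kurtosis(x) == pytest.approx(1.0)

    def test_kurtosis_of_gaussian_is_three(self):
        x = np.random.default_rng(11).standard_normal(200_000)
        assert F.kurtosis(x) == pytest.approx(3.0, abs=0.05)

    def test_kurtosis_amplitude_invariant(self):
        x = np.random.default_rng(2).standard_normal(500)
        assert F.kurtosis(100.0 * x) == pytest.approx(F.kurtosis(x))

    def test_degenerate_inputs_error(self):
        with pytest.raises(DegenerateSignalError):
            F.kurtosis(np.ones(100))
        with pytest.raises(ValueError):
            F.line_length(np.array([1.0]))


class TestTrackSummaries:
    def test_constant_track(self):
        s = F.summarize_track(np.full(29, 4.2))
        assert s["p95"] == pytest.approx(4.2)
        assert s["min"] == 4.2
        assert s["mean"] == pytest.approx(4.2)
        assert s["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_on_1_to_29(self):
        s = F.summarize_track(np.arange(1.0, 30.0))
        assert s["min"] == 1.0 and s["mean"] == 15.0
        # linear-interpolated 95th percentile of 1..29: 1 + 0.95*28 = 27.6
        assert s["p95"] == pytest.approx(27.6)

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            F.summarize_track(np.array([]))


class TestEogEmg:
    def test_slow_eog_band_captures_1hz(self):
        x = _sine(1.0, dur_s=4.0, amp=50.0)
        total = np.mean((x - x.mean()) ** 2)
        assert F.eog_band_energy(x, FS) > 0.9 * total

    def test_slow_eog_band_rejects_20hz(self):
        x = _sine(20.0, dur_s=4.0, amp=50.0)
        total = np.mean((x - x.mean()) ** 2)
        assert F.eog_band_energy(x, FS) < 0.1 * total

    def test_emg_energy_closed_forms(self):
        assert F.emg_energy(np.zeros(100)) == 0.0
        assert F.emg_energy(np.full(100, 9.0)) == 0.0  # DC rejected
        assert F.emg_energy(np.tile([3.0, -3.0], 50)) == pytest.approx(9.0)


class TestRatiosAndAveraging:
    def test_ratio_values(self):
        r = F.power_ratios({"delta": 0.4, "theta": 0.2, "alpha": 0.2})
        assert r["delta_theta_ratio"] == pytest.approx(2.0)
        assert r["theta_alpha_ratio"] == pytest.approx(1.0)

    def test_zero_denominator_stays_finite(self):
        r = F.power_ratios({"delta": 0.3, "theta": 0.0, "alpha": 0.0}, eps=1e-12)
        assert np.isfinite(r["delta_theta_ratio"])
        assert r["delta_theta_ratio"] > 1e10

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_contralateral_average_symmetric_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(29), rng.standard_normal(29)
        np.testing.assert_allclose(
            F.contralateral_average(a, b), F.contralateral_average(b, a)
        )
        np.testing.assert_allclose(F.contralateral_average(a, a), a)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            F.contralateral_average(np.zeros(29), np.zeros(28))


def _stage_record(occ_freq: float, n_epochs: int = 3, amp: float = 30.0, seed: int = 0):
    """Record whose occipital leads carry a pure-band rhythm plus weak noise."""
    rng = np.random.default_rng(seed)
    n = int(n_epochs * 30 * FS)
    t = np.arange(n) / FS
    channels = []
    for lab in MONTAGE_LABELS:
        x = 2.0 * rng.standard_normal(n)
        if lab in ("O1-M2", "O2-M1"):
            x = x + amp * np.sin(2 * np.pi * occ_freq * t)
        channels.append(ChannelSignal(lab, x, FS))
    return PolysomnogramRecord("s", channels)


class TestExtractFeatures:
    def test_shape_and_determinism(self):
        rec = _stage_record(10.0, n_epochs=4)
        fs1 = F.extract_features(rec)
        fs2 = F.extract_features(rec)
        assert fs1.matrix.shape == (4, len(F.feature_layout()))
        np.testing.assert_array_equal(fs1.matrix, fs2.matrix)
        assert np.isfinite(fs1.matrix).all()

    def test_left_right_swap_invariance(self):
        rec = _stage_record(10.0, n_epochs=2)
        swapped_labels = {
            "F3-M2": "F4-M1", "F4-M1": "F3-M2", "C3-M2": "C4-M1", "C4-M1": "C3-M2",
            "O1-M2": "O2-M1", "O2-M1": "O1-M2", "EOG-L": "EOG-R", "EOG-R": "EOG-L",
            "chin-EMG": "chin-EMG",
        }
        swapped = PolysomnogramRecord(
            "s", [ChannelSignal(swapped_labels[c.label], c.samples, c.fs) for c in rec.channels]
        )
        np.testing.assert_allclose(
            F.extract_features(rec).matrix, F.extract_features(swapped).matrix
        )

    def test_alpha_vs_delta_dominance_separates_wake_from_deep_sleep(self):
        names = F.feature_layout()
        i_alpha = names.index("occipital_alpha_frac_mean")
        i_delta = names.index("occipital_delta_frac_mean")
        wake_like = F.extract_features(_stage_record(10.0)).matrix
        deep_like = F.extract_features(_stage_record(1.5)).matrix
        assert wake_like[:, i_alpha].mean() > deep_like[:, i_alpha].mean()
        assert deep_like[:, i_delta].mean() > wake_like[:, i_delta].mean()

    def test_band_fractions_amplitude_invariant(self):
        rec = _stage_record(10.0, n_epochs=2)
        scaled = PolysomnogramRecord(
            "s", [ChannelSignal(c.label, 10.0 * c.samples, c.fs) for c in rec.channels]
        )
        names = F.feature_layout()
        frac_cols = [i for i, n in enumerate(names) if "_frac_" in n or "_ratio_" in n]
        a = F.extract_features(rec).matrix
        b = F.extract_features(scaled).matrix
        np.testing.assert_allclose(a[:, frac_cols], b[:, frac_cols], rtol=1e-9)
        # while line length scales linearly
        ll_cols = [i for i, n in enumerate(names) if "_line_length_mean" in n]
        np.testing.assert_allclose(b[:, ll_cols], 10.0 * a[:, ll_cols], rtol=1e-9)

    def test_missing_channel_errors_by_name(self):
        rec = _stage_record(10.0, n_epochs=1)
        partial = PolysomnogramRecord("s", [c for c in rec.channels if c.label != "chin-EMG"])
        with pytest.raises(ConfigurationError, match="chin-EMG"):
            F.extract_features(partial)

    def test_dead_channel_epoch_flagged_and_zero_filled(self):
        rec = _stage_record(10.0, n_epochs=2)
        dead = []
        for c in rec.channels:
            x = c.samples.copy()
            if c.label.startswith(("F", "C", "O")):
                x[: int(30 * FS)] = 0.0  # first epoch dead on EEG
            dead.append(ChannelSignal(c.label, x, c.fs))
        fs = F.extract_features(PolysomnogramRecord("s", dead))
        assert fs.epoch_flags.tolist() == [True, False]
        assert np.all(fs.matrix[0] == 0.0)

    def test_tsv_round_trip(self, tmp_path):
        fs = F.extract_features(_stage_record(10.0, n_epochs=2))
        path = tmp_path / "f.tsv"
        F.write_features_tsv(fs, path)
        back = F.read_features_tsv(path)
        assert back.names == fs.names
        np.testing.assert_allclose(back.matrix, fs.matrix, rtol=1e-9, atol=1e-12)
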