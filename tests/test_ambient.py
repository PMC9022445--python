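import numpy as np
import pandas as pd
import pytest

from pamkit.ambient import (DegenerateAudioError, Waveform, a_automated,
                            a_manual, _windowed_log10_rms, fold_range,
                            read_wav, rms_log10, variance_components,
                            write_wav)
from pamkit.ingest import SelectionTable
from pamkit.simulate import SongEvent, SoundscapeSpec, simulate_audio


def _empty_selections():
    return SelectionTable(pd.DataFrame(
        columns=["selection", "begin_s", "end_s", "low_hz", "high_hz", "species"]
    ))


class TestRmsLog10:
    def test_sine_closed_form(self):
        t = np.arange(44100) / 44100
        wave = 0.5 * np.sin(2 * np.pi * 440 * t)
        assert rms_log10(wave) == pytest.approx(np.log10(0.5 / np.sqrt(2)), abs=1e-4)

    def test_constant_snip_signaled(self):
        with pytest.raises(DegenerateAudioError):
            rms_log10(np.ones(1000))
        assert rms_log10(np.ones(1000), on_constant="neginf") == -np.inf

    def test_white_noise_sampling_bound(self):
        # chi^2 sampling error of the variance at n = 44100 keeps the
        # log10 RMS within 0.01 of log10(sigma)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, 44100)
        assert rms_log10(x) == pytest.approx(-2.0, abs=0.01)

    def test_dc_offset_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.01, 44100)
        assert rms_log10(x + 0.5) == pytest.approx(rms_log10(x), abs=1e-12)


class TestAAutomated:
    def test_window_count_at_defaults(self):
        # one 60 s minute at rate 1000: floor((60 - 1)/0.1) + 1 = 591 windows
        vals = _windowed_log10_rms(np.random.default_rng(0).normal(size=60_000),
                                   win=1000, step=100)
        assert vals.size == 591

    def test_recovers_stationary_sigma(self):
        rng = np.random.default_rng(2)
        wave = Waveform(rng.normal(0, 0.02, 2 * 60 * 8000), rate=8000)
        est = a_automated(wave)
        assert len(est.per_minute_quiet) == 2
        assert est.a_value == pytest.approx(np.log10(0.02), abs=0.02)

    def test_percentile_robust_to_sparse_tones(self):
        rng = np.random.default_rng(3)
        rate = 8000
        x = rng.normal(0, 0.02, 2 * 60 * rate)
        for minute in range(2):  # 2 one-second loud bursts per minute (~3% duty)
            for k in (10, 35):
                i0 = (minute * 60 + k) * rate
                x[i0:i0 + rate] += 0.5 * np.sin(2 * np.pi * 3000 *
                                                np.arange(rate) / rate)
        est = a_automated(Waveform(x, rate))
        assert est.a_value == pytest.approx(np.log10(0.02), abs=0.02)

    def test_amplitude_scaling_shifts_by_log10_c(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.01, 60 * 8000)
        base = a_automated(Waveform(x, 8000)).a_value
        scaled = a_automated(Waveform(10 * x, 8000)).a_value
        assert scaled == pytest.approx(base + 1.0, abs=1e-9)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            a_automated(Waveform(np.zeros(1000), 8000))


class TestAManual:
    def test_one_snip_per_minute_without_selections(self):
        rng = np.random.default_rng(5)
        wave = Waveform(rng.normal(0, 0.02, 3 * 60 * 8000), rate=8000)
        est = a_manual(wave, _empty_selections(), seed=11)
        assert len(est.per_minute_quiet) == 3
        # snips start at the seeded random offsets inside their own minutes
        for m, t in enumerate(est.snip_times):
            assert m * 60 <= t < (m + 1) * 60

    def test_fully_occupied_minute_rolls_forward(self):
        rng = np.random.default_rng(6)
        wave = Waveform(rng.normal(0, 0.02, 2 * 60 * 8000), rate=8000)
        sel = SelectionTable(pd.DataFrame({
            "selection": [1], "begin_s": [0.0], "end_s": [60.0],
            "low_hz": [0.0], "high_hz": [8000.0], "species": ["AAA"],
        }))
        est = a_manual(wave, sel, seed=3)
        assert all(t >= 60.0 for t in est.snip_times)

    def test_no_free_second_anywhere_rejected(self):
        rng = np.random.default_rng(7)
        wave = Waveform(rng.normal(0, 0.02, 60 * 8000), rate=8000)
        sel = SelectionTable(pd.DataFrame({
            "selection": [1], "begin_s": [0.0], "end_s": [60.0],
            "low_hz": [0.0], "high_hz": [8000.0], "species": ["AAA"],
        }))
        with pytest.raises(ValueError, match="free second"):
            a_manual(wave, sel, seed=3)

    def test_agrees_with_automated_on_annotated_audio(self):
        spec = SoundscapeSpec(
            duration_s=180, rate=22050, background_sigma=0.02,
            songs=[SongEvent(onset_s=10 + 20 * k, duration_s=1.5,
                             center_hz=4000, amplitude=0.3) for k in range(8)],
        )
        wave, sel = simulate_audio(spec, seed=9)
        manual = a_manual(wave, sel, seed=1).a_value
        auto = a_automated(wave).a_value
        assert manual == pytest.approx(auto, abs=0.05)


class TestVarianceComponents:
    @staticmethod
    def _simulate(shares, n_loc=10, n_occ=20, n_min=10, years=(2016, 2018), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        total = 1.0
        sd_occ, sd_loc, sd_min = (np.sqrt(total * s) for s in shares)
        for year in years:
            occ_eff = rng.normal(0, sd_occ, n_occ)
            loc_eff = rng.normal(0, sd_loc, n_loc)
            for o in range(n_occ):
                for l in range(n_loc):
                    eps = rng.normal(0, sd_min, n_min)
                    for m in range(n_min):
                        rows.append({"year": year, "location": f"L{l}",
                                     "occasion": f"{year}-{o}", "minute": m,
                                     "value": occ_eff[o] + loc_eff[l] + eps[m]})
        return pd.DataFrame(rows)

    def test_day_dominated_data_gives_full_occasion_share(self):
        rows = []
        for o, level in enumerate([0.0, 1.0, 5.0]):
            for l in range(2):
                for m in range(4):
                    rows.append({"year": 2018, "location": l, "occasion": o,
                                 "minute": m, "value": level})
        vc = variance_components(pd.DataFrame(rows))
        assert vc.occasion == pytest.approx(1.0)
        assert vc.location == pytest.approx(0.0)

    def test_recovers_known_shares(self):
        df = self._simulate((0.85, 0.04, 0.11), seed=42)
        vc = variance_components(df)
        assert vc.occasion == pytest.approx(0.85, abs=0.05)
        assert vc.location == pytest.approx(0.04, abs=0.05)
        assert vc.minute == pytest.approx(0.11, abs=0.05)

    def test_constant_data_signaled(self):
        df = self._simulate((0, 0, 0), n_loc=2, n_occ=2, n_min=2, years=(2018,))
        df["value"] = 1.0
        with pytest.raises(DegenerateAudioError):
            variance_components(df)

    def test_single_level_rejected(self):
        df = self._simulate((0.5, 0.3, 0.2), n_loc=1, n_occ=3, n_min=2,
                            years=(2018,))
        with pytest.raises(ValueError, match="2 locations"):
            variance_components(df)


class TestFoldRange:
    def test_simple_ratio(self):
        out = fold_range({"d1": 1.0, "d2": 4.0})
        assert out.loc["d2", "fold_over_min"] == pytest.approx(4.0)

    def test_log_values_after_delogging(self):
        out = fold_range({"d1": 10**-2, "d2": 10**-1})
        assert out.loc["d2", "fold_over_min"] == pytest.approx(10.0)

    def test_equal_values_fold_one(self):
        out = fold_range({"a": 2.0, "b": 2.0, "c": 2.0})
        assert (out["fold_over_min"] == 1.0).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_range({"a": 0.0, "b": 1.0})


def test_wav_round_trip_and_mono_mixdown(tmp_path):
    rng = np.random.default_rng(8)
    x = np.clip(rng.normal(0, 0.1, 8000), -1, 1)
    write_wav(Waveform(x, 8000), tmp_path / "a.wav")
    back = read_wav(tmp_path / "a.wav")
    assert back.rate == 8000
    np.testing.assert_allclose(back.samples, x, atol=1 / 32767)
    stereo = Waveform(np.stack([x, -x], axis=1), 8000)
    assert np.allclose(stereo.samples, 0.0)
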