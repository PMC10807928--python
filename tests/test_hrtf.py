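"""Sweep deconvolution, gain/DTF/ILD spectra, ITD extraction, morphometry."""

import numpy as np
import pytest

from voleabr.hrtf import (GainSpectrum, ImpulseResponse, MorphometrySet,
                          analyze_scene, compute_dtf, compute_gain,
                          compute_ild, deconvolve_sweep, effective_diameter,
                          estimate_itd, ir_to_spectrum, octave_smooth,
                          path_length_for_itd, predict_max_itd)
from voleabr.synth import (HeadModel, SweepSpec, generate_hrtf_scene,
                           sweep_signal)

SPEC = SweepSpec(n_points=2**15)
IN_BAND = (500.0, 18000.0)


class TestDeconvolution:
    def test_sweep_itself_gives_peak_at_zero_lag(self):
        ir = deconvolve_sweep(sweep_signal(SPEC), SPEC)
        assert ir.peak_lag() == 0

    def test_delayed_sweep_gives_peak_at_delay(self):
        x = sweep_signal(SPEC).samples
        delayed = np.concatenate([np.zeros(100), x])
        ir = deconvolve_sweep(delayed, SPEC)
        assert ir.peak_lag() == 100

    def test_two_tap_filter_recovered_in_band(self):
        """A known 2-tap system comes back within 1% over the sweep band."""
        taps = np.zeros(64)
        taps[0], taps[30] = 1.0, 0.5
        x = sweep_signal(SPEC).samples
        rec = np.convolve(x, taps)
        ir = deconvolve_sweep(rec, SPEC, out_len=2048, pre=256)
        seg = ir.samples[ir.lag0 - 128 : ir.lag0 + 512]
        nfft = 4096
        got = np.fft.rfft(seg, nfft) * np.exp(
            2j * np.pi * np.fft.rfftfreq(nfft) * 128
        )
        f = np.fft.rfftfreq(nfft, 1 / SPEC.fs)
        want = 1.0 + 0.5 * np.exp(-2j * np.pi * f * 30 / SPEC.fs)
        band = (f >= IN_BAND[0]) & (f <= IN_BAND[1])
        np.testing.assert_allclose(np.abs(got[band]), np.abs(want[band]), rtol=0.01)

    def test_fs_mismatch_rejected(self):
        from voleabr.synth import Waveform

        with pytest.raises(ValueError, match="sampling"):
            deconvolve_sweep(Waveform(np.zeros(100), fs=48000.0), SPEC)


class TestGain:
    GRID = np.linspace(0, 22050, 257)

    def spec(self, gains):
        return GainSpectrum(freqs_hz=self.GRID, gain_db=gains)

    def test_identical_spectra_give_zero_gain(self):
        a = self.spec(np.random.default_rng(0).standard_normal(257))
        out = compute_gain(a, a)
        np.testing.assert_allclose(out.gain_db, 0.0, atol=1e-12)

    def test_flat_offset_preserved(self):
        cal = self.spec(np.zeros(257))
        out = compute_gain(self.spec(np.full(257, 6.0)), cal)
        np.testing.assert_allclose(out.gain_db, 6.0)

    def test_grid_mismatch_rejected(self):
        a = self.spec(np.zeros(257))
        b = GainSpectrum(freqs_hz=self.GRID[:-1], gain_db=np.zeros(256))
        with pytest.raises(ValueError, match="grid"):
            compute_gain(a, b)

    def test_scene_gain_matches_head_shelf_within_1db(self):
        """Recovered right-ear gain at +90 deg equals the generator's
        frequency shadow to within 1 dB across the measured band."""
        head = HeadModel()
        scene = generate_hrtf_scene(head, [90], SPEC)
        cal_ir = deconvolve_sweep(scene.calibration, SPEC)
        ear_ir = deconvolve_sweep(scene.right[90][0], SPEC)
        gain = compute_gain(ir_to_spectrum(ear_ir), ir_to_spectrum(cal_ir))
        f = gain.freqs_hz
        band = (f >= IN_BAND[0]) & (f <= IN_BAND[1])
        expected = head.max_ild_db / 2.0 * f**2 / (f**2 + head.shadow_corner_hz**2)
        assert np.max(np.abs(gain.gain_db[band] - expected[band])) < 1.0


class TestOctaveSmooth:
    GRID = np.fft.rfftfreq(512, 1 / 44100.0)

    def test_flat_spectrum_unchanged(self):
        s = GainSpectrum(freqs_hz=self.GRID, gain_db=np.full(257, 3.0))
        out = octave_smooth(s)
        np.testing.assert_allclose(out.gain_db, 3.0, atol=1e-9)

    def test_single_bin_spike_mass_conserved(self):
        g = np.zeros(257)
        k = np.argmin(np.abs(self.GRID - 8000.0))
        g[k] = 20.0
        s = GainSpectrum(freqs_hz=self.GRID, gain_db=g)
        out = octave_smooth(s, fraction=1 / 12)  # wide enough to spread
        power_in = np.sum(10 ** (g[1:] / 10.0) - 1.0)
        power_out = np.sum(10 ** (out.gain_db[1:] / 10.0) - 1.0)
        assert power_out == pytest.approx(power_in, rel=0.01)
        assert out.gain_db[k] < 20.0  # actually spread

    def test_double_smoothing_is_one_wider_pass(self):
        rng = np.random.default_rng(4)
        g = np.cumsum(rng.standard_normal(257)) * 0.3
        s = GainSpectrum(freqs_hz=self.GRID, gain_db=g)
        twice = octave_smooth(octave_smooth(s, 1 / 48), 1 / 48)
        once = octave_smooth(s, np.sqrt(2) / 48)
        band = self.GRID > 500
        assert np.max(np.abs(twice.gain_db[band] - once.gain_db[band])) < 0.2

    def test_bad_fraction_rejected(self):
        s = GainSpectrum(freqs_hz=self.GRID, gain_db=np.zeros(257))
        with pytest.raises(ValueError):
            octave_smooth(s, fraction=0.0)


class TestDtfIld:
    GRID = np.fft.rfftfreq(512, 1 / 44100.0)

    def gains(self, per_az):
        return {az: GainSpectrum(freqs_hz=self.GRID, gain_db=np.asarray(g, float))
                for az, g in per_az.items()}

    def test_identical_positions_give_zero_dtfs(self):
        g = np.random.default_rng(0).standard_normal(257)
        dtfs = compute_dtf(self.gains({az: g for az in range(-90, 91, 10)}))
        for d in dtfs.values():
            np.testing.assert_allclose(d.gain_db, 0.0, atol=1e-12)

    def test_single_hot_position_splits_19_to_minus_1(self):
        per_az = {az: np.zeros(257) for az in range(-90, 91, 10)}
        hot = np.zeros(257)
        hot[40] = 19.0
        per_az[0] = hot
        dtfs = compute_dtf(self.gains(per_az))
        assert dtfs[0].gain_db[40] == pytest.approx(18.0)
        assert dtfs[90].gain_db[40] == pytest.approx(-1.0)

    def test_per_frequency_mean_is_zero(self):
        rng = np.random.default_rng(3)
        dtfs = compute_dtf(self.gains(
            {az: rng.standard_normal(257) * 5 for az in range(-90, 91, 10)}
        ))
        mean = np.mean([d.gain_db for d in dtfs.values()], axis=0)
        assert np.max(np.abs(mean)) < 0.01

    def test_front_notch_survives_mean_removal(self):
        """A 16 kHz notch present only near the midline stays visible in the
        DTFs at those positions."""
        k = np.argmin(np.abs(self.GRID - 16000.0))
        per_az = {az: np.zeros(257) for az in range(-90, 91, 10)}
        for az in (-20, -10, 0, 10, 20):
            per_az[az] = per_az[az].copy()
            per_az[az][k] = -15.0
        dtfs = compute_dtf(self.gains(per_az))
        for az in (-20, 0, 20):
            assert dtfs[az].gain_db[k] < -10.0
        assert dtfs[90].gain_db[k] > 0.0

    def test_single_position_rejected(self):
        with pytest.raises(ValueError, match="two positions"):
            compute_dtf(self.gains({0: np.zeros(257)}))

    def test_ild_examples(self):
        left = GainSpectrum(freqs_hz=self.GRID, gain_db=np.zeros(257))
        right = GainSpectrum(freqs_hz=self.GRID, gain_db=np.full(257, 6.0))
        np.testing.assert_allclose(compute_ild(right, left).gain_db, 6.0)
        np.testing.assert_allclose(compute_ild(left, left).gain_db, 0.0)


def brute_force_lag(a, b):
    """Exhaustive integer-lag search maximizing sum a[n] * b[n - lag]."""
    best_lag, best_val = 0, -np.inf
    for lag in range(-(b.size - 1), a.size):
        lo = max(0, lag)
        hi = min(a.size, b.size + lag)
        v = float(np.dot(a[lo:hi], b[lo - lag : hi - lag]))
        if v > best_val:
            best_val, best_lag = v, lag
    return best_lag


class TestEstimateItd:
    FS = 44100.0

    def ir(self, samples, lag0=0):
        return ImpulseResponse(np.asarray(samples, float), self.FS, lag0=lag0)

    def test_identical_irs_give_zero(self):
        x = np.random.default_rng(0).standard_normal(256)
        assert estimate_itd(self.ir(x), self.ir(x)) == pytest.approx(0.0, abs=1e-9)

    def test_right_delayed_is_negative(self):
        """Right ear lagging by 0.1 ms -> ITD = -0.1 ms."""
        x = np.zeros(512)
        x[50] = 1.0
        d = int(round(0.1e-3 * self.FS))
        y = np.roll(x, d)
        itd = estimate_itd(self.ir(x), self.ir(y), interpolate=False)
        assert itd == pytest.approx(-d / self.FS * 1000.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_lag_search(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal(1024)
        shift = rng.integers(-40, 40)
        right = np.roll(base, shift) + 0.05 * rng.standard_normal(1024)
        got = estimate_itd(self.ir(base), self.ir(right), interpolate=False)
        want = -brute_force_lag(right, base) / self.FS * 1000.0
        assert got == pytest.approx(want, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_itd(self.ir(np.zeros(64)), self.ir(np.ones(64)))


class TestMorphometry:
    def test_reference_male_head_predicts_76us(self):
        m = MorphometrySet(pinna_width_mm=10.7, pinna_length_mm=13.2,
                           inter_pinna_mm=15.3)
        assert predict_max_itd(m) == pytest.approx(75.8, abs=0.05)

    def test_80us_path_is_27mm(self):
        assert path_length_for_itd(80.0) == pytest.approx(27.44, abs=0.005)

    def test_round_trip_exact(self):
        m = MorphometrySet(pinna_width_mm=10.45, pinna_length_mm=13.0,
                           inter_pinna_mm=16.99)
        back = path_length_for_itd(predict_max_itd(m))
        assert abs(back - (10.45 + 16.99)) < 1e-9

    def test_effective_diameter_reference_female(self):
        assert round(effective_diameter(13.0, 10.2), 1) == 11.5

    def test_effective_diameter_circle_and_product(self):
        assert effective_diameter(7.0, 7.0) == pytest.approx(7.0)
        assert effective_diameter(14.5, 9.2) == pytest.approx(np.sqrt(133.4))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_diameter(0.0, 5.0)
        m = MorphometrySet(10.0, 13.0, 15.0)
        with pytest.raises(ValueError):
            predict_max_itd(m, c_m_s=-1.0)


class TestScenePipeline:
    def test_delay_curve_recovered_and_odd(self):
        head = HeadModel()
        azimuths = [-90, -50, 0, 50, 90]
        cues = analyze_scene(generate_hrtf_scene(head, azimuths, SPEC))
        sample_ms = 1000.0 / SPEC.fs
        for az in azimuths:
            expected = head.max_itd_s * np.sin(np.radians(az)) * 1000.0
            assert cues.itd_ms[az] == pytest.approx(expected, abs=0.25 * sample_ms)
            assert cues.itd_ms[az] == pytest.approx(-cues.itd_ms[-az], abs=sample_ms)

    def test_ild_odd_and_dtf_mean_zero(self):
        cues = analyze_scene(generate_hrtf_scene(HeadModel(), [-90, -30, 0, 30, 90], SPEC))
        band = cues.gain_left[0].band(500.0, 18000.0)
        np.testing.assert_allclose(
            cues.ild[90].gain_db[band], -cues.ild[-90].gain_db[band], atol=0.5
        )
        mean_dtf = np.mean([cues.dtf_left[a].gain_db for a in cues.azimuths], axis=0)
        assert np.max(np.abs(mean_dtf)) < 0.01
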