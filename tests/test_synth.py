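"""Generator behavior: determinism, convergence, injected-structure fidelity."""

import numpy as np
import pytest
from scipy.signal import argrelmax

from voleabr import synth
from voleabr.abr import average_epochs
from voleabr.conditions import AZIMUTH_GRID_DEG, StimulusCondition
from voleabr.synth import (ABRSimConfig, BICParams, HeadModel, SweepSpec,
                           WaveParams, generate_abr_epochs,
                           generate_binaural_session, generate_hrtf_scene,
                           generate_level_series, sweep_signal)


def flat_config(**kw):
    waves = {w: WaveParams(0.0, lat) for w, lat in
             zip("I II III IV".split(), (2.0, 3.0, 3.7, 4.8))}
    defaults = dict(wave_params=waves, noise_sd_uv=1.0, n_epochs=10)
    defaults.update(kw)
    return ABRSimConfig(**defaults)


class TestEpochGeneration:
    def test_identical_seeds_bit_identical(self, click_left):
        cfg = synth.female_click_config(n_epochs=20, seed=42)
        a = generate_abr_epochs(cfg, click_left)
        b = generate_abr_epochs(cfg, click_left)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_conditions_get_independent_noise(self, click_left):
        cfg = flat_config(seed=42)
        a = generate_abr_epochs(cfg, click_left)
        b = generate_abr_epochs(cfg, StimulusCondition("right", "click", 90.0))
        assert not np.array_equal(a.samples, b.samples)

    def test_zero_amplitude_zero_noise_gives_flat_epoch(self):
        cfg = flat_config(noise_sd_uv=0.0, n_epochs=1)
        ep = generate_abr_epochs(cfg, StimulusCondition("left", "click", 90.0))
        assert np.all(ep.samples == 0.0)

    def test_epoch_geometry(self, noiseless_female, click_left):
        ep = generate_abr_epochs(noiseless_female, click_left)
        assert ep.n_samples == round(12.0 * 97656.25 / 1000.0)
        assert ep.fs == 97656.25

    def test_binaural_condition_rejected(self, noiseless_female):
        cond = StimulusCondition("binaural", "click", 90.0, itd_ms=0.0)
        with pytest.raises(ValueError, match="monaural"):
            generate_abr_epochs(noiseless_female, cond)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            flat_config(wave_params={"I": WaveParams(-1.0, 2.0)})

    def test_noiseless_average_peaks_at_reference_latencies(
        self, noiseless_female, click_left
    ):
        """Averaged noise-free female trace has local maxima at the group
        mean latencies, to sample resolution."""
        ep = generate_abr_epochs(noiseless_female, click_left)
        trace = average_epochs(ep)
        t = trace.time_ms()
        maxima = t[argrelmax(trace.values)[0]]
        dt = 1000.0 / ep.fs
        for expected in (2.02, 2.98, 3.71, 4.83):
            assert np.min(np.abs(maxima - expected)) <= dt

    @pytest.mark.parametrize("n", [100, 400, 1600])
    def test_averaged_noise_shrinks_as_sqrt_n(self, n):
        """SD of the noise-only average follows sigma / sqrt(n)."""
        cfg = flat_config(noise_sd_uv=1.0, n_epochs=n, seed=7)
        ep = generate_abr_epochs(cfg, StimulusCondition("left", "click", 90.0))
        sd = ep.samples.mean(axis=0).std()
        assert sd == pytest.approx(1.0 / np.sqrt(n), rel=0.10)


class TestBinauralSession:
    def test_additivity_when_dn1_zero(self):
        zero_bic = BICParams(amplitude={0.0: 0.0}, latency={0.0: 4.5})
        cfg = flat_config(noise_sd_uv=0.0, n_epochs=1, bic_params=zero_bic,
                          wave_params={"I": WaveParams(3.0, 2.0),
                                       "II": WaveParams(2.0, 3.0),
                                       "III": WaveParams(1.0, 3.7),
                                       "IV": WaveParams(2.5, 4.8)})
        (left, right, binaural), = generate_binaural_session(cfg, [0.0]).values()
        np.testing.assert_allclose(
            binaural.samples.mean(axis=0),
            left.samples.mean(axis=0) + right.samples.mean(axis=0),
            atol=1e-12,
        )

    def test_injected_dn1_latency_matches_reference_row(self, noiseless_male):
        """At 0 ITD the injected deflection sits at the reported 4.5 ms."""
        session = generate_binaural_session(noiseless_male, [0.0])
        left, right, binaural = session[0.0]
        residual = binaural.samples.mean(axis=0) - (
            left.samples.mean(axis=0) + right.samples.mean(axis=0)
        )
        t = np.arange(residual.size) / noiseless_male.fs * 1000.0
        assert t[np.argmin(residual)] == pytest.approx(4.5, abs=1000.0 / noiseless_male.fs)
        assert residual.min() == pytest.approx(-3.0, rel=1e-3)

    def test_injected_latency_increases_with_itd(self, noiseless_male):
        itds = [0.0, 0.5, 1.0, 1.5, 2.0]
        session = generate_binaural_session(noiseless_male, itds)
        lats = []
        for itd in itds:
            left, right, binaural = session[itd]
            residual = binaural.samples.mean(axis=0) - (
                left.samples.mean(axis=0) + right.samples.mean(axis=0)
            )
            t = np.arange(residual.size) / noiseless_male.fs * 1000.0
            lats.append(t[np.argmin(residual)])
        assert all(np.diff(lats) > 0)

    def test_off_grid_itd_rejected(self, noiseless_male):
        with pytest.raises(ValueError, match="grid"):
            generate_binaural_session(noiseless_male, [0.3])


class TestLevelSeries:
    def test_below_threshold_epochs_are_noise_only(self):
        cfg = synth.female_click_config(
            noise_sd_uv=0.0, n_epochs=1, threshold_db=55.0
        )
        series = generate_level_series(
            cfg, range(90, 0, -10), StimulusCondition("left", "click", 90.0)
        )
        for level, ep in series.items():
            if level < 55.0:
                assert np.all(ep.samples == 0.0)
            else:
                assert np.abs(ep.samples).max() > 0

    def test_growth_scaling_matches_growth_function(self):
        cfg = synth.female_click_config(noise_sd_uv=0.0, n_epochs=1, threshold_db=50.0)
        series = generate_level_series(
            cfg, [90, 80, 70], StimulusCondition("left", "click", 90.0)
        )
        peak90 = np.abs(series[90.0].samples).max()
        peak70 = np.abs(series[70.0].samples).max()
        expected = synth.linear_db_growth(70, 50) / synth.linear_db_growth(90, 50)
        assert peak70 / peak90 == pytest.approx(expected, rel=1e-9)

    def test_reference_threshold_lookup_best_frequency(self):
        """The male reference audiogram bottoms out at 25 dB SPL at 8 kHz."""
        cfg = synth.male_click_config()
        cond = StimulusCondition("left", "tone", 90.0, frequency_khz=8.0)
        assert cfg.resolve_threshold(cond) == 25.0

    def test_empty_and_misspaced_levels_rejected(self, noiseless_female, click_left):
        with pytest.raises(ValueError):
            generate_level_series(noiseless_female, [], click_left)
        with pytest.raises(ValueError, match="10 dB"):
            generate_level_series(noiseless_female, [90, 85], click_left)


def zero_crossing_freq(x, fs):
    idx = np.nonzero(np.diff(np.signbit(x)))[0]
    return fs / (2.0 * np.mean(np.diff(idx)))


class TestSweep:
    def test_endpoint_frequencies(self):
        spec = SweepSpec(n_points=2**17)
        x = sweep_signal(spec).samples
        n_seg = int(0.05 * spec.fs)
        assert zero_crossing_freq(x[:n_seg], spec.fs) == pytest.approx(250, rel=0.1)
        assert zero_crossing_freq(x[-n_seg:], spec.fs) == pytest.approx(20000, rel=0.1)

    def test_level_dbfs_sets_peak_amplitude(self):
        x = sweep_signal(SweepSpec()).samples
        assert np.abs(x).max() == pytest.approx(10 ** (-15 / 20), rel=0.01)

    def test_doubling_duration_keeps_endpoints(self):
        long_spec = SweepSpec(duration_s=6.0, n_points=2**18)
        x = sweep_signal(long_spec).samples
        n_seg = int(0.05 * long_spec.fs)
        assert zero_crossing_freq(x[:n_seg], long_spec.fs) == pytest.approx(250, rel=0.1)
        assert zero_crossing_freq(x[-n_seg:], long_spec.fs) == pytest.approx(20000, rel=0.1)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SweepSpec(f_end_hz=23000.0)


class TestScene:
    SPEC = SweepSpec(n_points=2**15)

    def test_midline_ears_identical(self):
        scene = generate_hrtf_scene(HeadModel(), [0], self.SPEC)
        np.testing.assert_allclose(scene.left[0], scene.right[0], atol=1e-12)

    def test_mirror_symmetry_swaps_ears(self):
        scene = generate_hrtf_scene(HeadModel(), [-30, 30], self.SPEC)
        np.testing.assert_allclose(scene.left[30], scene.right[-30], atol=1e-12)
        np.testing.assert_allclose(scene.right[30], scene.left[-30], atol=1e-12)

    def test_calibration_is_head_independent(self):
        small = generate_hrtf_scene(HeadModel(inter_pinna_mm=10.0), [0], self.SPEC)
        large = generate_hrtf_scene(HeadModel(inter_pinna_mm=20.0), [0], self.SPEC)
        np.testing.assert_array_equal(small.calibration, large.calibration)

    def test_off_grid_azimuth_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            generate_hrtf_scene(HeadModel(), [45], self.SPEC)

    def test_full_grid_has_19_positions(self):
        scene = generate_hrtf_scene(HeadModel(), AZIMUTH_GRID_DEG, self.SPEC)
        assert len(scene.azimuths) == 19


class TestAnimalDraws:
    def test_draw_preserves_latency_order(self):
        base = synth.female_click_config()
        for seed in range(30):
            cfg = synth.draw_animal(base, seed)
            lats = [cfg.wave_params[w].latency_ms for w in ("I", "II", "III", "IV")]
            assert all(np.diff(lats) > 0)
            assert all(p.amplitude_uv >= 0 for p in cfg.wave_params.values())

    def test_draw_marginals_match_population(self):
        base = synth.female_click_config()
        amps = [synth.draw_animal(base, s).wave_params["I"].amplitude_uv
                for s in range(400)]
        ref = base.wave_params["I"]
        assert np.mean(amps) == pytest.approx(ref.amplitude_uv, abs=0.15)
        assert np.std(amps) == pytest.approx(ref.amplitude_sd, rel=0.2)

    def test_symmetric_preset_peaks_at_zero(self):
        p = synth.symmetric_bic_params("male")
        itds = sorted(p.amplitude)
        assert max(p.amplitude, key=p.amplitude.get) == 0.0
        assert min(p.latency, key=p.latency.get) == 0.0
        for i in itds:
            assert p.amplitude[i] == pytest.approx(p.amplitude[-i])
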