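"""Simulator physics: kinematics, projection, phase and chirp synthesis."""

import numpy as np
import pytest

from mdcpr import (
    SPEED_OF_LIGHT,
    CompressionScenario,
    KinematicsTrace,
    RadarConfig,
    SubjectProfile,
    chirp_level_synthesize,
    phase_synthesize,
    project_radial,
    range_process,
    simulate_kinematics,
)
from mdcpr.synthetic import generate_campaign, record_signal


class TestRadarConfig:
    def test_derived_quantities(self, config):
        assert config.wavelength_m == pytest.approx(3.8934e-3, rel=1e-4)
        assert config.prf_hz == 2000.0
        assert config.frequency_slope_hz_s == pytest.approx(3.99e9 / 50e-6)
        # c/(2B) for B = 3.99 GHz; the nominal-4-GHz value 3.75 cm is not forced
        assert config.range_resolution_m == pytest.approx(0.03757, abs=1e-5)

    @pytest.mark.parametrize(
        "field,value",
        [("carrier_frequency_hz", 0.0), ("bandwidth_hz", -1.0), ("chirp_duration_s", 0.0)],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            RadarConfig(**{field: value})


class TestKinematics:
    def test_zero_depth_is_flat(self, config, clean_profile):
        sc = CompressionScenario(
            target_depth_cm=0.0, subject_profile=clean_profile, duration_s=5.0
        )
        tr = simulate_kinematics(sc, config)
        assert np.all(tr.displacement_m == 0.0)
        assert np.all(tr.velocity_m_s == 0.0)
        assert tr.per_cycle_truth.empty

    def test_peak_velocity_closed_form(self, config, clean_profile):
        # raised sine: v_peak = pi D / T_c, checked against numerical gradient
        sc = CompressionScenario(
            target_depth_cm=5.0, rate_cpm=100.0, duration_s=6.0,
            subject_profile=clean_profile,
        )
        tr = simulate_kinematics(sc, config)
        v_expect = np.pi * 0.05 / 0.6
        assert tr.velocity_m_s.max() == pytest.approx(v_expect, rel=1e-6)
        v_num = np.gradient(tr.displacement_m, tr.time_s)
        assert v_num.max() == pytest.approx(v_expect, rel=1e-3)
        # peak Doppler 2 v / lambda ~ 134.5 Hz
        assert 2 * v_expect / config.wavelength_m == pytest.approx(134.5, abs=0.5)

    def test_cycle_count_and_truth(self, config, clean_profile):
        sc = CompressionScenario(
            target_depth_cm=5.0, rate_cpm=110.0, duration_s=30.0,
            subject_profile=clean_profile,
        )
        tr = simulate_kinematics(sc, config)
        assert len(tr.per_cycle_truth) == 55  # floor(30 * 110 / 60)
        assert np.allclose(tr.per_cycle_truth["depth_cm"], 5.0)
        assert np.all(tr.displacement_m >= 0.0)

    def test_per_cycle_truth_matches_waveform(self, config):
        prof = SubjectProfile(depth_bias_cm=0.3, depth_jitter_sd_cm=0.2, rate_jitter_sd_cpm=2.0)
        sc = CompressionScenario(
            target_depth_cm=4.0, rate_cpm=100.0, duration_s=10.0,
            subject_profile=prof, rng_seed=5,
        )
        tr = simulate_kinematics(sc, config)
        for _, row in tr.per_cycle_truth.iterrows():
            m = (tr.time_s >= row["start_s"]) & (tr.time_s < row["end_s"])
            assert tr.displacement_m[m].max() * 100 == pytest.approx(row["depth_cm"], rel=1e-3)

    def test_determinism(self, config):
        sc = CompressionScenario(target_depth_cm=5.0, duration_s=5.0, rng_seed=11)
        a = simulate_kinematics(sc, config)
        b = simulate_kinematics(sc, config)
        assert np.array_equal(a.displacement_m, b.displacement_m)

    def test_aliasing_guard(self, clean_profile):
        slow_cfg = RadarConfig(slow_time_interval_s=5e-3)  # PRF 200 Hz
        sc = CompressionScenario(
            target_depth_cm=6.0, rate_cpm=110.0, subject_profile=clean_profile
        )
        with pytest.raises(ValueError, match="alias"):
            simulate_kinematics(sc, slow_cfg)

    @pytest.mark.parametrize("bad", [{"target_depth_cm": -1.0}, {"rate_cpm": 0.0},
                                     {"duration_s": -2.0}, {"aspect_angle_deg": 90.0}])
    def test_invalid_scenarios_rejected(self, bad):
        with pytest.raises(ValueError):
            CompressionScenario(**bad)


class TestProjection:
    def test_zero_angle_identity(self, make_signal, config, clean_profile):
        sc = CompressionScenario(target_depth_cm=5.0, duration_s=3.0,
                                 subject_profile=clean_profile)
        tr = simulate_kinematics(sc, config)
        assert np.array_equal(project_radial(tr, 0.0).displacement_m, tr.displacement_m)

    @pytest.mark.parametrize("theta,peak_cm", [(60.0, 2.5), (30.0, 4 * np.cos(np.pi / 6))])
    def test_cosine_scaling(self, config, clean_profile, theta, peak_cm):
        depth = 5.0 if theta == 60.0 else 4.0
        sc = CompressionScenario(target_depth_cm=depth, duration_s=3.0,
                                 subject_profile=clean_profile)
        tr = simulate_kinematics(sc, config)
        rad = project_radial(tr, theta)
        assert rad.displacement_m.max() * 100 == pytest.approx(peak_cm, rel=1e-6)

    def test_monotone_in_angle(self, config, clean_profile):
        sc = CompressionScenario(target_depth_cm=5.0, duration_s=2.0,
                                 subject_profile=clean_profile)
        tr = simulate_kinematics(sc, config)
        peaks = [project_radial(tr, th).displacement_m.max() for th in range(0, 90, 15)]
        assert np.all(np.diff(peaks) < 0)
        for th, pk in zip(range(0, 90, 15), peaks):
            assert pk == pytest.approx(tr.displacement_m.max() * np.cos(np.deg2rad(th)), rel=1e-2)

    def test_rejects_90_degrees(self, config, clean_profile):
        sc = CompressionScenario(target_depth_cm=5.0, duration_s=1.0,
                                 subject_profile=clean_profile)
        tr = simulate_kinematics(sc, config)
        with pytest.raises(ValueError):
            project_radial(tr, 90.0)


class TestPhaseSynthesis:
    def test_constant_displacement_is_dc(self, config):
        n = 2000
        tr = KinematicsTrace(np.arange(n) / 2000.0, np.full(n, 0.01), np.zeros(n),
                             None, 2000.0)
        sig = phase_synthesize(tr, config)
        spec = np.abs(np.fft.fft(sig.samples))
        assert np.argmax(spec) == 0

    def test_linear_displacement_doppler_line(self, config):
        # f = 2 v / lambda for v = 0.1 m/s
        n = 4000
        t = np.arange(n) / 2000.0
        tr = KinematicsTrace(t, 0.1 * t, np.full(n, 0.1), None, 2000.0)
        sig = phase_synthesize(tr, config)
        freqs = np.fft.fftfreq(n, 1 / 2000.0)
        peak = freqs[np.argmax(np.abs(np.fft.fft(sig.samples)))]
        f_expect = 2 * 0.1 / config.wavelength_m  # ~51.37 Hz
        assert abs(peak - f_expect) <= 2000.0 / n  # within one bin
        assert peak > 0  # motion away from radar -> positive Doppler

    def test_phase_excursion_per_cycle(self, make_signal, config):
        sig, _ = make_signal(depth_cm=5.0, duration_s=3.0)
        ph = np.unwrap(np.angle(sig.samples))
        expected = 4 * np.pi * 0.05 / config.wavelength_m  # ~161.4 rad
        assert ph.max() - ph.min() == pytest.approx(expected, rel=1e-9)

    def test_noise_determinism(self, make_signal):
        a, _ = make_signal(noise_snr_db=15.0, seed=3)
        b, _ = make_signal(noise_snr_db=15.0, seed=3)
        assert np.array_equal(a.samples, b.samples)
        c, _ = make_signal(noise_snr_db=15.0, seed=4)
        assert not np.array_equal(a.samples, c.samples)


class TestChirpLevel:
    def test_static_target_beat_frequency(self, config):
        n = 50
        tr = KinematicsTrace(np.arange(n) / 2000.0, np.zeros(n), np.zeros(n), None, 2000.0)
        cube = chirp_level_synthesize(tr, config, standoff_range_m=0.5)
        assert cube.samples.shape == (128, 3, n)
        spec = np.abs(np.fft.rfft(cube.samples[:, 0, :], axis=0))
        peaks = np.argmax(spec[1:], axis=0) + 1
        assert np.all(peaks == peaks[0])  # constant across frames
        fb_expect = config.frequency_slope_hz_s * 2 * 0.5 / SPEED_OF_LIGHT
        df = config.fast_time_sample_rate_hz / config.samples_per_chirp
        assert abs(peaks[0] * df - fb_expect) <= df

    def test_quarter_wavelength_phase_step(self, config):
        lam_c = config.center_wavelength_m
        disp = np.array([0.0, lam_c / 4])
        tr = KinematicsTrace(np.arange(2) / 2000.0, disp, np.zeros(2), None, 2000.0)
        slow = range_process(chirp_level_synthesize(tr, config, 0.5))
        dphi = np.angle(slow.samples[1] / slow.samples[0])
        assert abs(abs(dphi) - np.pi) < 0.02

    def test_phase_consistency_between_paths(self, config, clean_profile):
        # same trace through both synthesis paths -> same slow-time phase
        sc = CompressionScenario(target_depth_cm=5.0, rate_cpm=100.0, duration_s=3.0,
                                 subject_profile=clean_profile, noise_snr_db=None)
        tr = simulate_kinematics(sc, config)
        slow = range_process(chirp_level_synthesize(tr, config, 0.5))
        ref = phase_synthesize(tr, config, wavelength_m=slow.wavelength_m)
        ph_a = np.unwrap(np.angle(slow.samples))
        ph_b = np.unwrap(np.angle(ref.samples))
        d = (ph_a - ph_a[0]) - (ph_b - ph_b[0])
        assert np.sqrt(np.mean(d**2)) < 1e-2

    def test_pure_noise_cube_warns(self, config):
        n = 30
        tr = KinematicsTrace(np.arange(n) / 2000.0, np.zeros(n), np.zeros(n), None, 2000.0)
        cube = chirp_level_synthesize(tr, config, 0.5)
        rng = np.random.default_rng(0)
        cube.samples = rng.standard_normal(cube.samples.shape)
        with pytest.warns(UserWarning, match="wanders"):
            range_process(cube)

    def test_static_scatterer_constant_modulus(self, config):
        n = 40
        tr = KinematicsTrace(np.arange(n) / 2000.0, np.zeros(n), np.zeros(n), None, 2000.0)
        slow = range_process(chirp_level_synthesize(tr, config, 0.5))
        mod = np.abs(slow.samples)
        assert mod.std() / mod.mean() < 1e-9

    def test_standoff_beyond_ambiguity_rejected(self, config):
        n = 2
        tr = KinematicsTrace(np.arange(n) / 2000.0, np.zeros(n), np.zeros(n), None, 2000.0)
        with pytest.raises(ValueError, match="unambiguous"):
            chirp_level_synthesize(tr, config, config.max_unambiguous_range_m * 1.1)


class TestCampaign:
    def test_full_campaign_record_count(self, config):
        man = generate_campaign(config, subjects=8, seed=1, duration_s=30.0)
        assert len(man) == 8 * 3 * 4 * 3  # 288 = 8 subjects x 36 conditions

    def test_manifest_determinism(self, config):
        a = generate_campaign(config, subjects=2, seed=9)
        b = generate_campaign(config, subjects=2, seed=9)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_single_record_sample_count(self, config):
        man = generate_campaign(
            config, subjects=1, cases={1: 0.0}, depths_cm=(5.0,), rates_cpm=(100.0,),
            seed=2, duration_s=30.0,
        )
        assert len(man) == 1
        sig, _ = record_signal(man.iloc[0], config)
        assert len(sig) == 60_000  # 30 s x 2000 Hz

    def test_empty_condition_lists_rejected(self, config):
        with pytest.raises(ValueError):
            generate_campaign(config, subjects=1, depths_cm=(), seed=0)
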