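import numpy as np
import pytest
from scipy.signal import find_peaks

from aquamyo.features import frequency_domain_features, power_spectrum
from aquamyo.io import TimeSeries
from aquamyo.segment import acc_magnitude
from aquamyo.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_imu_trace,
    generate_semg_burst,
    trapezoid_envelope,
)


def burst_mnf(burst: TimeSeries) -> float:
    S = power_spectrum(burst)
    mnf, _, _ = frequency_domain_features(S)
    return mnf


class TestSemgBurst:
    def test_zero_amplitude_gives_silence(self, rng):
        burst = generate_semg_burst(1.0, 1000.0, 0.0, 80.0, 25.0, rng=rng)
        assert np.all(burst.samples == 0.0)

    def test_fixed_seed_is_bit_identical(self):
        a = generate_semg_burst(2.0, 1000.0, 0.5, 80.0, 25.0,
                                rng=np.random.default_rng(3))
        b = generate_semg_burst(2.0, 1000.0, 0.5, 80.0, 25.0,
                                rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_semg_burst(1.0, 200.0, 0.5, 80.0, 25.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_semg_burst(0.0, 1000.0, 0.5, 80.0, 25.0)

    def test_mean_frequency_near_spectral_center(self):
        # flat envelope: the empirical MNF should sit at the configured
        # center frequency over repeated realizations
        mnfs = [
            burst_mnf(generate_semg_burst(10.0, 1000.0, 0.4, 80.0, 25.0,
                                          rng=np.random.default_rng(s)))
            for s in range(10)
        ]
        assert np.mean(mnfs) == pytest.approx(80.0, abs=3.0)

    def test_plateau_rms_amplitude_contract(self):
        # mean plateau RMS over >= 20 seeds within 2% of the request
        target = 0.6
        rmss = [
            np.sqrt(np.mean(
                generate_semg_burst(5.0, 1000.0, target, 80.0, 25.0,
                                    rng=np.random.default_rng(s)).samples ** 2
            ))
            for s in range(25)
        ]
        assert np.mean(rmss) == pytest.approx(target, rel=0.02)

    def test_long_burst_spectral_convergence(self):
        # at 60 s the MNF converges to the center within bandwidth/10
        mnfs = [
            burst_mnf(generate_semg_burst(60.0, 1000.0, 0.4, 80.0, 25.0,
                                          rng=np.random.default_rng(s)))
            for s in range(3)
        ]
        assert abs(np.mean(mnfs) - 80.0) <= 2.5


class TestTrapezoidEnvelope:
    def test_onsets_and_plateau(self):
        env, onsets = trapezoid_envelope(3000, 3, active_fraction=0.8)
        assert list(onsets) == [0, 1000, 2000]
        assert env.max() == pytest.approx(1.0)
        assert env[1400] == pytest.approx(1.0)  # mid-plateau of rep 2

    def test_fatigue_decay_scales_last_rep(self):
        env, onsets = trapezoid_envelope(4000, 4, fatigue_decay=0.2)
        first = env[onsets[0]:onsets[0] + 700].max()
        last = env[onsets[3]:onsets[3] + 700].max()
        assert first == pytest.approx(1.0)
        assert last == pytest.approx(0.8)


class TestImuTrace:
    def test_noiseless_pulse_count(self):
        trace = generate_imu_trace(3, 30.0, 1000.0, rng=np.random.default_rng(0))
        mag = acc_magnitude((
            trace.acc[0], trace.acc[1],
            TimeSeries(trace.acc[2].samples - 1.0, 1000.0),  # strip gravity
        ))
        peaks, _ = find_peaks(mag.samples, height=0.5, distance=5000)
        assert len(peaks) == 3

    def test_env_scale_scales_magnitude_exactly(self):
        a = generate_imu_trace(3, 30.0, 1000.0, env_scale=1.0,
                               rng=np.random.default_rng(0))
        b = generate_imu_trace(3, 30.0, 1000.0, env_scale=0.95,
                               rng=np.random.default_rng(0))

        def macc(tr):
            g = np.sqrt(tr.acc[0].samples ** 2 + tr.acc[1].samples ** 2
                        + (tr.acc[2].samples - 1.0) ** 2)
            return g.mean()

        assert macc(b) / macc(a) == pytest.approx(0.95, abs=1e-9)

    def test_default_macc_within_published_range(self):
        trace = generate_imu_trace(3, 30.0, 1000.0, rng=np.random.default_rng(1))
        g = np.sqrt(trace.acc[0].samples ** 2 + trace.acc[1].samples ** 2
                    + (trace.acc[2].samples - 1.0) ** 2)
        assert 1.0 <= g.mean() <= 6.0

    def test_infeasible_timing_rejected(self):
        with pytest.raises(ValueError):
            generate_imu_trace(100, 1.0, 1000.0)

    def test_ground_truth_onsets_returned(self):
        trace = generate_imu_trace(4, 20.0, 1000.0, rng=np.random.default_rng(0))
        assert list(trace.onsets) == [0, 5000, 10000, 15000]


class TestCohort:
    def test_trial_counting(self):
        cohort = generate_cohort(15, GeneratorConfig())
        assert len(cohort) == 15 * 2 * 2 * 3 * 5  # 900

    def test_fixed_seed_cohort_is_bit_identical(self, small_config):
        a = generate_cohort(2, small_config)
        b = generate_cohort(2, small_config)
        ra = a.materialize(a.trials[5])
        rb = b.materialize(b.trials[5])
        np.testing.assert_array_equal(ra.semg.samples, rb.semg.samples)
        np.testing.assert_array_equal(ra.acc[0].samples, rb.acc[0].samples)

    def test_degenerate_variance_gives_identical_parameters(self):
        cfg = GeneratorConfig(between_subject_sd=0.0, within_subject_sd=0.0,
                              subject_spectral_sd_hz=0.0)
        cohort = generate_cohort(3, cfg)
        profiles = cohort.subjects
        assert len({p.amplitude_factor for p in profiles}) == 1
        assert len({p.mvc_amplitude_mv for p in profiles}) == 1
        assert len({p.spectral_offset_hz for p in profiles}) == 1

    def test_subject_effects_shared_across_environments(self, small_config):
        cohort = generate_cohort(1, small_config)
        land = [t for t in cohort.trials if t.environment == "land"][0]
        aqua = [t for t in cohort.trials if t.environment == "aquatic"][0]
        rl, ra = cohort.materialize(land), cohort.materialize(aqua)
        assert rl.mvc_reference_mv == ra.mvc_reference_mv

    def test_annotations_carry_timeline_and_onsets(self, small_config):
        cohort = generate_cohort(1, small_config)
        rec = cohort.materialize(cohort.trials[0])
        assert rec.annotation_indices("contraction_start") == [5000]
        assert len(rec.annotation_indices("rep_onset")) == rec.reps_target

    def test_manifest_lists_every_trial(self, small_config):
        cohort = generate_cohort(2, small_config)
        manifest = cohort.manifest()
        assert len(manifest["trials"]) == len(cohort)
        entry = manifest["trials"][0]
        assert len(entry["true_onsets"]) == entry["reps"]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(rest_duration_s=0.0)
        with pytest.raises(ValueError):
            GeneratorConfig(reps_options=())
        with pytest.raises(ValueError):
            GeneratorConfig(aquatic_acc_scale=0.0)
        with pytest.raises(ValueError):
            GeneratorConfig(spectral_center_hz=400.0)
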