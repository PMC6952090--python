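import numpy as np
import pytest

from pupiltag.calibration import DEFAULT_CALIBRATION, fit_exponential
from pupiltag.preprocess import demean, preprocess, smooth, trim_onset
from pupiltag.simulate import (
    PupilModelParams,
    gain,
    generate_dataset,
    manifest,
    read_dataset,
    simulate_trial,
    write_dataset,
)
from pupiltag.spectrum import peak_frequency, periodogram, psd_at
from pupiltag.stimulus import (
    EXP1_FREQUENCIES,
    make_exp1_layout,
    make_exp2a_layout,
    make_exp2b_layout,
)


def demeaned_prep(trace):
    """Trim + smooth + mean removal, keeping absolute PSD scale."""
    return demean(smooth(trim_onset(trace, 1.0), 120.0))


class TestGain:
    def test_anchor_at_one_hz(self, canonical_params):
        assert gain(canonical_params, 1.0) == canonical_params.gain_at_1hz

    def test_exponential_ratio_closed_form(self, canonical_params):
        g = canonical_params.gain_decay
        ratio = gain(canonical_params, 0.75) / gain(canonical_params, 2.75)
        assert ratio == pytest.approx(np.exp(-g * 2.0))

    def test_rolloff_beyond_tracking_cutoff(self, canonical_params):
        smooth_extrap = canonical_params.gain_at_1hz * np.exp(
            canonical_params.gain_decay * (3.5 - 1.0)
        )
        assert gain(canonical_params, 3.5) < 0.1 * smooth_extrap

    def test_rejects_nonpositive_frequency(self, canonical_params):
        with pytest.raises(ValueError):
            gain(canonical_params, 0.0)


class TestSimulateTrial:
    def test_trace_length_rule(self, canonical_params):
        tr = simulate_trial(make_exp1_layout(1.0), "stim", 8.0,
                            sampling_rate=333.0, params=canonical_params, seed=0)
        assert len(tr) == round(8.0 * 333.0)

    def test_same_seed_same_trace(self, canonical_params):
        lay = make_exp2b_layout()
        a = simulate_trial(lay, "key3", 8.0, params=canonical_params, seed=99)
        b = simulate_trial(lay, "key3", 8.0, params=canonical_params, seed=99)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_trial_peaks_at_gazed_frequency(self, quiet_params):
        tr = simulate_trial(make_exp1_layout(1.25), "stim", 10.0,
                            params=quiet_params, seed=0)
        spec = periodogram(preprocess(tr))
        assert peak_frequency(spec, (0.1, 3.5)) == pytest.approx(1.25, abs=0.01)

    def test_unknown_gazed_id_rejected(self, canonical_params):
        with pytest.raises(KeyError):
            simulate_trial(make_exp1_layout(1.0), "nope", 8.0,
                           params=canonical_params, seed=0)

    def test_gazed_beats_leaked_component(self, canonical_params):
        lay = make_exp2a_layout(1.0, 0.25)
        wins = 0
        for seed in range(100):
            tr = simulate_trial(lay, "L", 8.0, params=canonical_params,
                                seed=seed)
            spec = periodogram(preprocess(tr))
            wins += psd_at(spec, 1.0) > psd_at(spec, 1.25)
        assert wins >= 99

    def test_band_noise_power_concentrated_in_band(self):
        params = PupilModelParams(white_noise_sd=0.0, gain_at_1hz=0.0,
                                  leakage=0.0, onset_dip=False)
        tr = simulate_trial(make_exp1_layout(1.0), "stim", 30.0,
                            params=params, seed=12)
        spec = periodogram(demean(tr))
        in_band = (spec.frequencies >= 0.13) & (spec.frequencies <= 0.42)
        assert spec.psd[in_band].sum() >= 0.90 * spec.psd.sum()

    def test_onset_dip_confined_to_trimmed_second(self, quiet_params):
        lay = make_exp1_layout(1.0)
        with_dip = simulate_trial(lay, "stim", 10.0, params=quiet_params, seed=0)
        no_dip = simulate_trial(
            lay, "stim", 10.0, seed=0,
            params=PupilModelParams(white_noise_sd=0.0, band_noise_amp=0.0,
                                    leakage=0.0, onset_dip=False),
        )
        after_trim = trim_onset(with_dip, 1.0).samples
        reference = trim_onset(no_dip, 1.0).samples
        assert np.allclose(after_trim, reference, atol=0.2)
        assert not np.allclose(with_dip.samples[:50], no_dip.samples[:50],
                               atol=0.2)


class TestEmergentCalibration:
    def test_fitted_decay_matches_twice_gain_decay(self, canonical_params):
        # mean PSD peak per frequency should follow exp(2 * gain_decay * f)
        rng = np.random.default_rng(11)
        freqs = np.array(EXP1_FREQUENCIES)
        mean_psd = []
        for f in freqs:
            lay = make_exp1_layout(f)
            vals = [
                psd_at(periodogram(demeaned_prep(
                    simulate_trial(lay, "stim", 10.0, params=canonical_params,
                                   seed=int(rng.integers(2**31))))), f)
                for _ in range(25)
            ]
            mean_psd.append(np.mean(vals))
        fit = fit_exponential(freqs, np.array(mean_psd))
        target = 2 * canonical_params.gain_decay
        assert abs(fit.b - target) / abs(target) < 0.15

    def test_correction_flattens_gazed_psd(self, canonical_params):
        # the property the exponential correction exists to create
        rng = np.random.default_rng(21)
        freqs = [f for f in EXP1_FREQUENCIES if 0.75 <= f <= 2.75]
        means = []
        for f in freqs:
            lay = make_exp1_layout(f)
            vals = [
                psd_at(periodogram(demeaned_prep(
                    simulate_trial(lay, "stim", 10.0, params=canonical_params,
                                   seed=int(rng.integers(2**31))))), f)
                * DEFAULT_CALIBRATION.weight(f)
                for _ in range(12)
            ]
            means.append(np.mean(vals))
        means = np.array(means)
        assert means.std() / means.mean() < 0.15


class TestGenerateDataset:
    def test_exp1_shape(self, canonical_params):
        trials = generate_dataset("exp1", 2, canonical_params, seed=0)
        assert len(trials) == 24
        assert all(t.meta["duration_s"] == 10.0 for t in trials)
        assert all(len(t.trace) == 3330 for t in trials)

    def test_exp2a_shape(self, canonical_params):
        trials = generate_dataset("exp2a", 1, canonical_params, seed=0)
        assert len(trials) == 48
        man = manifest(trials)
        assert set(man["delta_f"]) == {0.06, 0.12, 0.25}
        assert set(man["gazed_id"]) == {"L", "R"}

    def test_exp2b_shape(self, canonical_params):
        trials = generate_dataset("exp2b", 1, canonical_params, seed=0)
        assert len(trials) == 12
        assert all(t.meta["duration_s"] == 8.0 for t in trials)

    def test_unknown_protocol_rejected(self, canonical_params):
        with pytest.raises(ValueError):
            generate_dataset("exp3", 1, canonical_params, seed=0)

    def test_dataset_reproducible_and_roundtrips(self, canonical_params,
                                                 tmp_path):
        a = generate_dataset("exp2b", 1, canonical_params, seed=5)
        b = generate_dataset("exp2b", 1, canonical_params, seed=5)
        assert all(np.array_equal(x.trace.samples, y.trace.samples)
                   for x, y in zip(a, b))
        write_dataset(a, tmp_path)
        back = read_dataset(tmp_path)
        assert len(back) == len(a)
        assert np.allclose(back[0].trace.samples, a[0].trace.samples,
                           atol=1e-5)
        assert back[0].meta["gazed_id"] == a[0].meta["gazed_id"]


class TestParamsValidation:
    def test_leakage_bounds(self):
        with pytest.raises(ValueError):
            PupilModelParams(leakage=1.0)

    def test_band_range_ordering(self):
        with pytest.raises(ValueError):
            PupilModelParams(band_noise_range=(0.4, 0.15))
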