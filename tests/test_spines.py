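import numpy as np
import pytest

from popdecode.population import wrap_orientation
from popdecode.spines import (
    EXPERIMENTAL_GRID,
    fit_tuning_gaussian,
    generate_spine_dataset,
    normalize_spine_responses,
    spine_inclusion_filter,
    subtract_bap,
    vector_strength,
    wrapped_gaussian,
)


class TestGenerator:
    def test_clean_spines_recover_ground_truth_tuning(self):
        ds = generate_spine_dataset(n_spines=5, noise_scale=1e-9,
                                    contamination_range=(0.0, 0.0), seed=1)
        for s in range(5):
            gt = ds.ground_truth.iloc[s]
            expected = wrapped_gaussian(ds.stimulus_grid, 0.0, gt.amplitude,
                                        gt.width_deg, gt.pref_deg)
            np.testing.assert_allclose(
                ds.spine_responses[s].mean(axis=0), expected, atol=1e-6)

    def test_full_contamination_zero_amplitude_copies_dendrite(self):
        ds = generate_spine_dataset(n_spines=3, amplitude_mean=0.0,
                                    amplitude_cv=0.0, noise_scale=1e-9,
                                    contamination_range=(1.0, 1.0), seed=2)
        for s in range(3):
            c = np.corrcoef(ds.spine_responses[s].ravel(),
                            ds.dendrite_signal.ravel())[0, 1]
            assert c > 0.999

    def test_default_sizing_matches_experiment(self):
        ds = generate_spine_dataset(seed=3)
        assert ds.n_spines == 159
        assert 8 <= ds.n_trials <= 10
        assert ds.stimulus_grid.size == 8
        assert np.allclose(np.diff(ds.stimulus_grid), 22.5)
        assert ds.blank_samples.shape[0] == ds.n_spines
        assert {"pref_deg", "amplitude", "contamination"} <= set(
            ds.ground_truth.columns)


class TestBapSubtraction:
    def test_zero_dendrite_is_noop(self):
        rng = np.random.default_rng(0)
        spine = rng.normal(size=(10, 8))
        corrected, s = subtract_bap(spine, np.zeros((10, 8)))
        assert s == 0.0
        np.testing.assert_array_equal(corrected, spine)

    def test_exact_mixture_recovered(self):
        ds = generate_spine_dataset(n_spines=1, seed=4)
        spine = 0.7 * ds.dendrite_signal
        corrected, s = subtract_bap(spine, ds.dendrite_signal)
        assert s == pytest.approx(0.7, abs=1e-9)
        assert np.abs(corrected).max() < 1e-9

    def test_recovery_under_noise_and_tuning(self):
        # spine = own tuning + 0.5 * dendrite + noise at SNR >= 3
        ds = generate_spine_dataset(n_spines=100,
                                    contamination_range=(0.5, 0.5),
                                    noise_scale=0.3, seed=5)
        errs = [subtract_bap(ds.spine_responses[s],
                             ds.dendrite_signal)[1] - 0.5
                for s in range(100)]
        assert abs(np.median(errs)) < 0.05
        assert np.median(np.abs(errs)) < 0.1

    def test_cotuned_uncontaminated_not_oversubtracted(self):
        # tuning resembling the dendrite must not inflate the scale
        ds = generate_spine_dataset(n_spines=60, pref_spread=5.0,
                                    pref_uniform_fraction=0.0,
                                    contamination_range=(0.0, 0.0),
                                    noise_scale=0.15, seed=6)
        scales = [subtract_bap(ds.spine_responses[s],
                               ds.dendrite_signal)[1]
                  for s in range(60)]
        assert np.median(scales) < 0.1


class TestInclusionFilter:
    def test_unresponsive_spines_fail_snr(self):
        ds = generate_spine_dataset(n_spines=100, amplitude_mean=0.0,
                                    amplitude_cv=0.0, noise_scale=0.12,
                                    contamination_range=(0.0, 0.0), seed=7)
        rep = spine_inclusion_filter(ds)
        assert rep.passed.mean() <= 0.05
        assert (rep.table.loc[~rep.table.passed, "reasons"]
                .str.contains("low_snr").all())

    def test_dendrite_copies_fail_correlation(self):
        ds = generate_spine_dataset(n_spines=5, amplitude_mean=0.0,
                                    amplitude_cv=0.0, noise_scale=0.01,
                                    contamination_range=(1.0, 1.0), seed=8)
        rep = spine_inclusion_filter(ds)
        assert not rep.passed.any()
        assert (rep.table.dendrite_corr > 0.4).all()

    def test_strong_clean_spines_pass(self):
        # strongly responsive, uncontaminated spines always clear the SNR
        # criterion; the only legitimate exclusions are spines whose own
        # tuning resembles the dendrite's (correlation criterion)
        ds = generate_spine_dataset(n_spines=50, amplitude_mean=1.5,
                                    amplitude_cv=0.0,
                                    pref_uniform_fraction=1.0,
                                    noise_scale=0.1,
                                    contamination_range=(0.0, 0.0), seed=9)
        rep = spine_inclusion_filter(ds)
        assert rep.table.snr_pass.all()
        weakly_coupled = rep.table.dendrite_corr < 0.4
        assert rep.passed[weakly_coupled].all()
        assert rep.passed.mean() >= 0.6


class TestTuningFit:
    def test_noiseless_recovery(self):
        curve = wrapped_gaussian(EXPERIMENTAL_GRID, 0.1, 1.0, 20.0, 30.0)
        fit = fit_tuning_gaussian(curve)
        assert fit.converged
        assert abs(wrap_orientation(fit.preferred_orientation - 30.0)) < 0.5

    def test_constant_input_flagged(self):
        fit = fit_tuning_gaussian(np.full((10, 8), 2.0))
        assert not fit.converged
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_recovery_and_bias_under_noise(self):
        # SNR 3 (noise = amplitude/3), 10 trials, many spines
        ds = generate_spine_dataset(n_spines=150, amplitude_mean=1.0,
                                    amplitude_cv=0.0, noise_scale=1 / 3,
                                    contamination_range=(0.0, 0.0), seed=10)
        signed = []
        for s in range(150):
            fit = fit_tuning_gaussian(ds.spine_responses[s])
            signed.append(wrap_orientation(
                fit.preferred_orientation - ds.ground_truth.pref_deg[s]))
        signed = np.array(signed)
        assert np.median(np.abs(signed)) < 10.0
        assert abs(np.median(signed)) < 2.0


class TestVectorStrength:
    def test_single_stimulus_is_one(self):
        r = np.zeros(8)
        r[2] = 3.0
        assert vector_strength(r) == pytest.approx(1.0)

    def test_flat_response_is_zero(self):
        assert vector_strength(np.full(8, 2.0)) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_hand_computed_value(self):
        grid = np.array([-90.0, -45.0, 0.0, 45.0])
        assert vector_strength(np.array([2.0, 1.0, 0.0, 1.0]),
                               grid) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 1, 8)
        assert vector_strength(r) == pytest.approx(vector_strength(17.0 * r))

    def test_negative_floored_with_warning(self):
        r = np.array([1.0, -0.5, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="flooring"):
            v = vector_strength(r)
        assert 0.0 <= v <= 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(np.zeros(8))


class TestNormalization:
    def test_peak_of_mean_curve_is_one(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(0.1, 3.0, size=(10, 8))
        norm, peak = normalize_spine_responses(r)
        assert norm.mean(axis=0).max() == pytest.approx(1.0)
        assert peak == pytest.approx(r.mean(axis=0).max())

    def test_shape_invariance_across_amplitudes(self):
        base = wrapped_gaussian(EXPERIMENTAL_GRID, 0.0, 1.0, 20.0, 10.0)
        n1, _ = normalize_spine_responses(np.tile(base, (5, 1)))
        n2, _ = normalize_spine_responses(np.tile(10 * base, (5, 1)))
        np.testing.assert_allclose(n1, n2)

    def test_commutes_with_trial_averaging(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.1, 3.0, size=(10, 8))
        norm, _ = normalize_spine_responses(r)
        mean_then_norm, _ = normalize_spine_responses(r.mean(axis=0))
        np.testing.assert_allclose(norm.mean(axis=0), mean_then_norm)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            normalize_spine_responses(-np.ones((5, 8)))
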