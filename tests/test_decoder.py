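import numpy as np
import pytest

from popdecode.decoder import (
    DecoderWeights,
    accuracy_sweep,
    circular_error,
    derive_weights,
    evaluate_accuracy,
    fit_weights_logistic,
    map_estimate,
    posterior,
    smooth_weights,
    summarize_sweep,
)
from popdecode.population import (
    InputPopulation,
    NeuronTuning,
    PopulationSpec,
    make_population,
    simulate_responses,
    tuning_curve,
)


class TestDeriveWeights:
    def test_identity_covariance_collapse(self, identity_cov_pop):
        w = derive_weights(identity_cov_pop)
        np.testing.assert_array_equal(
            w.weights, identity_cov_pop.mean_response_matrix)

    def test_hand_solved_two_neuron_case(self):
        neurons = [NeuronTuning(0.0, 4.0, 4.0, 0.0),
                   NeuronTuning(0.0, 2.0, 4.0, 0.0)]
        spec = PopulationSpec(n_neurons=2, n_stimuli=2, seed=0)
        pop = InputPopulation(
            neurons=neurons,
            mean_response_matrix=np.array([[4.0, 2.0], [4.0, 2.0]]),
            correlation_matrix=np.eye(2),
            covariance_matrix=np.diag([2.0, 1.0]),
            spec=spec,
        )
        w = derive_weights(pop)
        np.testing.assert_allclose(w.weights[0], [2.0, 2.0])
        assert w.offsets[0] == pytest.approx(-6.0 + np.log(0.5))

    def test_solve_residual_invariant(self, hom_pop, het_pop):
        for pop in (hom_pop, het_pop):
            w = derive_weights(pop)
            resid = w.weights @ pop.covariance_matrix \
                - pop.mean_response_matrix
            scale = np.abs(pop.mean_response_matrix).max()
            assert np.abs(resid).max() / scale < 1e-8

    def test_diagonal_covariance_is_snr(self):
        neurons = [NeuronTuning(0.5, 3.0, 2.0, p) for p in (-30.0, 40.0)]
        spec = PopulationSpec(n_neurons=2, n_stimuli=4, seed=0)
        grid = spec.stimulus_grid
        f = np.column_stack([tuning_curve(n, grid) for n in neurons])
        q = np.diag([2.5, 0.5])
        pop = InputPopulation(neurons=neurons, mean_response_matrix=f,
                              correlation_matrix=np.eye(2),
                              covariance_matrix=q, spec=spec)
        w = derive_weights(pop)
        np.testing.assert_allclose(w.weights, f / np.diag(q), rtol=1e-10)

    def test_weight_profile_shape_homogeneous(self):
        # smooth central peak, negative flanks, near zero at orthogonal
        pop = make_population(PopulationSpec(
            n_neurons=1000, kind="homogeneous", max_correlation=0.25,
            n_stimuli=8, seed=7))
        w = derive_weights(pop)
        k0 = w.class_index(0.0)
        row = w.weights[k0]
        phi = pop.preferences
        central = row[np.abs(phi) < 5]
        flank = row[(np.abs(phi) > 20) & (np.abs(phi) < 40)]
        ortho = row[np.abs(np.abs(phi) - 90) < 10]
        assert central.min() > 0
        assert flank.mean() < 0
        assert np.abs(ortho).max() < 0.2 * central.max()

    def test_non_normalized_prior_warns(self, identity_cov_pop):
        with pytest.warns(UserWarning, match="prior"):
            w = derive_weights(identity_cov_pop, prior=np.array([1.0, 1.0,
                                                                 2.0, 1.0]))
        assert w.prior.sum() == pytest.approx(1.0)


class TestPosterior:
    def test_equal_logits_uniform(self):
        w = DecoderWeights(weights=np.zeros((4, 3)), offsets=np.zeros(4),
                           prior=np.full(4, 0.25),
                           stimulus_grid=np.array([-90., -45., 0., 45.]))
        p = posterior(w, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(p.probabilities, 0.25)

    def test_two_class_closed_form(self):
        w = DecoderWeights(weights=np.zeros((2, 1)),
                           offsets=np.array([0.0, np.log(3.0)]),
                           prior=np.array([0.5, 0.5]),
                           stimulus_grid=np.array([-90.0, 0.0]))
        p = posterior(w, np.array([0.0]))
        np.testing.assert_allclose(p.probabilities[0], [0.25, 0.75])

    def test_offset_shift_invariance_and_normalization(self, hom_pop):
        w = derive_weights(hom_pop)
        r = simulate_responses(hom_pop, 20, seed=1).responses[:, 0, :]
        p1 = posterior(w, r)
        w.offsets = w.offsets + 123.456
        p2 = posterior(w, r)
        np.testing.assert_allclose(p1.probabilities, p2.probabilities,
                                   atol=1e-12)
        np.testing.assert_allclose(p1.probabilities.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_length_mismatch_rejected(self, hom_pop):
        w = derive_weights(hom_pop)
        with pytest.raises(ValueError):
            posterior(w, np.zeros(5))


class TestMapAndError:
    def test_argmax_and_tie_break(self):
        from popdecode.decoder import PosteriorTable

        grid = np.array([-45.0, 0.0, 45.0])
        p = PosteriorTable(
            probabilities=np.array([[0.1, 0.8, 0.1], [0.5, 0.5, 0.0]]),
            map_indices=np.array([1, 0]))
        est = map_estimate(p, grid)
        assert est[0] == 0.0
        assert est[1] == -45.0  # exact tie -> lowest index

    def test_noiseless_map_identifies_every_stimulus(self, het_pop):
        w = derive_weights(het_pop)
        p = posterior(w, het_pop.mean_response_matrix)
        np.testing.assert_array_equal(p.map_indices,
                                      np.arange(het_pop.stimulus_grid.size))

    @pytest.mark.parametrize("est, true, expected", [
        (30.0, 30.0, 0.0),
        (80.0, -80.0, np.deg2rad(20.0) ** 2),  # wraps across +-90
        (45.0, -45.0, (np.pi / 2) ** 2),       # orthogonal = max error
    ])
    def test_wrapped_squared_error(self, est, true, expected):
        assert circular_error([est], [true])[0] == pytest.approx(expected)

    def test_error_bounded(self):
        rng = np.random.default_rng(2)
        e = circular_error(rng.uniform(-90, 90, 500),
                           rng.uniform(-90, 90, 500))
        assert np.all(e >= 0) and np.all(e <= (np.pi / 2) ** 2 + 1e-12)


class TestSmoothing:
    def test_no_smoothing_sentinel_is_identity(self, het_pop):
        w = derive_weights(het_pop)
        assert smooth_weights(w, 0.0, 0.0, het_pop.preferences) is w

    def test_progressive_smoothing_reduces_roughness(self):
        pop = make_population(PopulationSpec(
            n_neurons=256, kind="heterogeneous", max_correlation=0.25,
            n_stimuli=16, seed=8))
        w = derive_weights(pop)
        order = np.argsort(pop.preferences)

        def roughness(row):
            return np.var(np.diff(row[order]))

        base = roughness(w.weights[8])
        levels = [roughness(
            smooth_weights(w, r1, r2, pop.preferences).weights[8])
            for r1, r2 in [(0.1, 1.0), (0.2, 2.0), (1.0, 10.0)]]
        assert base > levels[0] > levels[1] > levels[2]

    def test_constant_profile_preserved(self, het_pop):
        w = derive_weights(het_pop)
        w.weights[0] = 3.14
        ws = smooth_weights(w, 0.5, 2.0, het_pop.preferences)
        np.testing.assert_allclose(ws.weights[0], 3.14, atol=1e-6)

    def test_parameter_domain(self, het_pop):
        w = derive_weights(het_pop)
        with pytest.raises(ValueError):
            smooth_weights(w, -1.0, 1.0, het_pop.preferences)
        with pytest.raises(ValueError):
            smooth_weights(w, 1.0, 0.0, het_pop.preferences)


class TestLogisticRoute:
    @pytest.fixture(scope="class")
    def small_pop_and_trials(self):
        pop = make_population(PopulationSpec(
            n_neurons=6, kind="homogeneous", max_correlation=0.25,
            n_stimuli=4, seed=5))
        rs = simulate_responses(pop, 10_000, seed=6)
        return pop, rs

    def test_rows_match_analytic(self, small_pop_and_trials):
        pop, rs = small_pop_and_trials
        wa = derive_weights(pop)
        wl = fit_weights_logistic(rs)
        for k in range(4):
            assert np.corrcoef(wa.weights[k], wl.weights[k])[0, 1] > 0.9

    def test_map_agreement_on_held_out(self, small_pop_and_trials):
        pop, rs = small_pop_and_trials
        wa = derive_weights(pop)
        wl = fit_weights_logistic(rs)
        held = simulate_responses(pop, 1000, seed=7).responses.reshape(-1, 6)
        agree = np.mean(posterior(wa, held).map_indices
                        == posterior(wl, held).map_indices)
        assert agree >= 0.95

    def test_deterministic_fit(self, small_pop_and_trials):
        _, rs = small_pop_and_trials
        w1 = fit_weights_logistic(rs)
        w2 = fit_weights_logistic(rs)
        np.testing.assert_array_equal(w1.weights, w2.weights)

    def test_shuffled_labels_shrink_weights(self, small_pop_and_trials):
        pop, rs = small_pop_and_trials
        rng = np.random.default_rng(0)
        n = rs.responses.shape[0] * rs.responses.shape[1]
        labels = rng.integers(0, 4, n)
        w = fit_weights_logistic(rs, labels=labels, ridge=1e-2)
        assert np.abs(w.weights).max() < 0.05

    def test_single_class_rejected(self, small_pop_and_trials):
        _, rs = small_pop_and_trials
        n = rs.responses.shape[0] * rs.responses.shape[1]
        with pytest.raises(ValueError):
            fit_weights_logistic(rs, labels=np.zeros(n, dtype=int))


class TestAccuracySweep:
    def test_sweep_table_and_determinism(self):
        kw = dict(kinds=("homogeneous",), n_grid=(8, 16),
                  c_o_grid=(0.0,), n_stimuli=8, n_eval_trials=20,
                  n_seeds=2, master_seed=4)
        df1 = accuracy_sweep(**kw)
        df2 = accuracy_sweep(**kw)
        assert len(df1) == 4
        np.testing.assert_array_equal(df1["mse"].values, df2["mse"].values)
        s = summarize_sweep(df1)
        assert {"mean_performance", "sem_performance"} <= set(s.columns)

    def test_performance_is_inverse_mse(self, hom_pop):
        w = derive_weights(hom_pop)
        acc = evaluate_accuracy(hom_pop, w, n_eval_trials=20, seed=3)
        assert acc.performance == pytest.approx(1.0 / max(acc.mse, 1e-12))
        assert np.all(acc.per_stimulus_mse >= 0)
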