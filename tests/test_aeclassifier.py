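"""Autoencoder classifier: forward pass, fitness, training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentumor.aeclassifier import (
    AEConfig,
    AEError,
    AEParams,
    ClassifierModel,
    ae_forward,
    classify,
    fitness_error_rate,
    reconstruction_error,
    train_mlo,
)
from pentumor.optimizers import MLOParams
from pentumor.phantoms import LabeledDataset, generate_feature_clusters


def _zero_params(config: AEConfig) -> AEParams:
    m, n = config.input_dim, config.latent_dim
    return AEParams(np.zeros((n, m)), np.zeros(n), np.zeros((m, n)), np.zeros(m))


class TestForwardPass:
    def test_zero_parameters_sigmoid_gives_half_everywhere(self):
        config = AEConfig(input_dim=4, latent_dim=2, activation="sigmoid")
        h, xp = ae_forward(np.array([1.0, -2.0, 0.5, 3.0]), _zero_params(config), config)
        assert np.all(h == 0.5)
        assert np.all(xp == 0.5)

    def test_relu_clamps_negative_preactivations(self):
        config = AEConfig(input_dim=3, latent_dim=1, activation="relu")
        params = _zero_params(config)
        params.enc_bias[:] = -5.0
        h, _ = ae_forward(np.ones(3), params, config)
        assert np.all(h == 0.0)

    def test_relu_identity_composition_on_subspace(self):
        # m=2, n=1 with selector/embedding weights: x = (a, 0) reconstructs
        # exactly for nonnegative a, so the reconstruction error is 0
        config = AEConfig(input_dim=2, latent_dim=1, activation="relu")
        params = AEParams(
            np.array([[1.0, 0.0]]), np.zeros(1), np.array([[1.0], [0.0]]), np.zeros(2)
        )
        x = np.array([0.75, 0.0])
        _, xp = ae_forward(x, params, config)
        assert np.array_equal(xp, x)
        assert reconstruction_error(x, xp) == 0.0

    def test_dimension_mismatch_rejected(self):
        config = AEConfig(input_dim=4, latent_dim=2)
        with pytest.raises(AEError):
            ae_forward(np.ones(3), _zero_params(config), config)

    def test_config_requires_compression(self):
        with pytest.raises(AEError):
            AEConfig(input_dim=4, latent_dim=4)
        assert AEConfig(input_dim=8).latent_dim == 2  # ceil(8/4)


class TestReconstructionError:
    def test_hand_values(self):
        assert reconstruction_error(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == 1.0
        x = np.array([0.3, -1.2])
        assert reconstruction_error(x, x) == 0.0

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.normal(size=(2, 6))
            assert reconstruction_error(a, b) >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(AEError):
            reconstruction_error(np.ones(3), np.ones(4))


class TestFitnessErrorRate:
    def test_hand_values(self):
        assert fitness_error_rate([0, 1, 0], [0, 1, 0]) == 0.0
        preds = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        labels = [0, 0, 0, 0, 0, 0, 0, 0, 0, 1]
        assert fitness_error_rate(preds, labels) == pytest.approx(40.0)
        assert fitness_error_rate([0] * 7 + [1] * 3, [0] * 10) == pytest.approx(30.0)

    def test_invariant_under_consistent_relabeling(self):
        preds = np.array([0, 1, 1, 0, 1])
        labels = np.array([0, 1, 0, 0, 1])
        assert fitness_error_rate(preds, labels) == fitness_error_rate(1 - preds, 1 - labels)

    def test_empty_input_rejected(self):
        with pytest.raises(AEError):
            fitness_error_rate([], [])


class TestParamFlattening:
    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_flatten_unflatten_round_trip(self, seed):
        config = AEConfig(input_dim=6, latent_dim=2)
        rng = np.random.default_rng(seed)
        vec = rng.normal(size=config.n_params)
        params = AEParams.from_flat(vec, config)
        assert np.array_equal(params.flatten(), vec)

    def test_param_count(self):
        config = AEConfig(input_dim=8, latent_dim=3)
        assert config.n_params == 2 * 8 * 3 + 8 + 3


class TestClassifierModel:
    def _tie_model(self, dim=4):
        config = AEConfig(input_dim=dim, latent_dim=1)
        return ClassifierModel(
            config=config,
            params_by_class={0: _zero_params(config), 1: _zero_params(config)},
            feature_min=np.zeros(dim),
            feature_max=np.ones(dim),
        )

    def test_equal_errors_tie_to_label_zero(self):
        model = self._tie_model()
        assert classify(np.array([0.2, 0.4, 0.6, 0.8]), model) == 0

    def test_argmin_reconstruction_rule(self):
        config = AEConfig(input_dim=2, latent_dim=1, activation="relu")
        perfect = AEParams(
            np.array([[1.0, 0.0]]), np.zeros(1), np.array([[1.0], [0.0]]), np.zeros(2)
        )
        model = ClassifierModel(
            config=config,
            params_by_class={0: _zero_params(config), 1: perfect},
            feature_min=np.zeros(2),
            feature_max=np.ones(2),
        )
        # (1, 0) is exactly reconstructible by the class-1 autoencoder only
        assert classify(np.array([1.0, 0.0]), model) == 1

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        data = generate_feature_clusters(15, dim=6, seed=2)
        model, _ = train_mlo(
            data, AEConfig(6, 2), MLOParams(population_size=10, max_iterations=10, seed=0)
        )
        x, _ = data.feature_matrix()
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ClassifierModel.from_json(path)
        assert np.array_equal(model.predict(x), loaded.predict(x))


class TestTrainMLO:
    def test_separable_fixture_reaches_low_error(self):
        data = generate_feature_clusters(30, dim=8, sd=1.0, seed=1)
        model, result = train_mlo(
            data, AEConfig(8, 3), MLOParams(population_size=20, max_iterations=40, seed=1)
        )
        assert result.best_fitness <= 5.0
        assert np.all(np.diff(result.best_trace) <= 0)

    def test_bit_reproducible(self):
        data = generate_feature_clusters(10, dim=6, seed=4)
        kwargs = dict(
            config=AEConfig(6, 2),
            mlo=MLOParams(population_size=10, max_iterations=15, seed=7),
        )
        m1, r1 = train_mlo(data, **kwargs)
        m2, r2 = train_mlo(data, **kwargs)
        assert np.array_equal(r1.best_trace, r2.best_trace)
        for label in (0, 1):
            assert np.array_equal(
                m1.params_by_class[label].flatten(), m2.params_by_class[label].flatten()
            )

    def test_single_class_rejected(self):
        data = generate_feature_clusters(5, dim=4, seed=0)
        one_class = LabeledDataset([(x, 0) for x, _ in data.items])
        with pytest.raises(AEError):
            train_mlo(one_class)

    def test_warm_start_stays_deterministic(self):
        data = generate_feature_clusters(10, dim=6, seed=4)
        kwargs = dict(
            config=AEConfig(6, 2),
            mlo=MLOParams(population_size=10, max_iterations=10, seed=2),
            warm_start=True,
        )
        _, r1 = train_mlo(data, **kwargs)
        _, r2 = train_mlo(data, **kwargs)
        assert np.array_equal(r1.best_trace, r2.best_trace)

    def test_fitness_bounded_in_percentage_scale(self):
        data = generate_feature_clusters(10, dim=6, seed=8)
        _, result = train_mlo(
            data, AEConfig(6, 2), MLOParams(population_size=8, max_iterations=10, seed=3)
        )
        assert 0.0 <= result.best_fitness <= 100.0 + 1e-6
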