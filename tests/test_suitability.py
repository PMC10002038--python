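import warnings

import numpy as np
import pytest

from greenscape.grid import LandCoverGrid
from greenscape.suitability import (
    ANNConfig,
    SuitabilityCube,
    predict_suitability,
    sample_training,
    suitability_rmse,
    train_suitability_model,
)
from greenscape.synth import SynthConfig, gen_drivers, gen_landscape


@pytest.fixture(scope="module")
def noiseless_scene():
    cfg = SynthConfig(seed=10, shape=(120, 120), driver_snr=np.inf, n_drivers=4,
                      class_proportions=(0.4, 0.3, 0.1, 0.08, 0.06, 0.04, 0.02))
    grid = gen_landscape(cfg)
    drivers = gen_drivers(grid, cfg).normalize()
    return grid, drivers


class TestSampleTraining:
    def test_rate_one_samples_every_cell(self, noiseless_scene):
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=1.0, seed=0)
        s = sample_training(grid, drivers, cfg)
        assert len(s.y) == grid.n_valid
        assert len(np.unique(s.X, axis=0)) <= grid.n_valid

    def test_sample_size_ceiling(self):
        cfg_s = SynthConfig(seed=0, shape=(200, 200))
        grid = gen_landscape(cfg_s)
        drivers = gen_drivers(grid, cfg_s).normalize()
        s = sample_training(grid, drivers, ANNConfig(sampling_rate=0.02, seed=1))
        assert len(s.y) == 800

    def test_deterministic_given_seed(self, noiseless_scene):
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=0.05, seed=3)
        a = sample_training(grid, drivers, cfg)
        b = sample_training(grid, drivers, cfg)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_unnormalized_drivers_rejected(self, noiseless_scene):
        grid, drivers = noiseless_scene
        raw = type(drivers)(layers=drivers.layers, normalized=False)
        with pytest.raises(ValueError):
            sample_training(grid, raw, ANNConfig())


class TestTrainAndPredict:
    def test_separable_classes_high_accuracy(self, noiseless_scene):
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=0.1, seed=0, max_epochs=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_suitability_model(
                sample_training(grid, drivers, cfg), cfg
            )
        cube = predict_suitability(model, drivers, grid)
        idx = grid.class_indices()[grid.valid_mask]
        acc = (cube.prob.argmax(axis=1) == idx).mean()
        assert acc >= 0.90

    def test_per_cell_sums_equal_one(self, noiseless_scene):
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=0.05, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_suitability_model(
                sample_training(grid, drivers, cfg), cfg
            )
        cube = predict_suitability(model, drivers, grid)
        np.testing.assert_allclose(cube.prob.sum(axis=1), 1.0, atol=1e-6)

    def test_uninformative_drivers_recover_priors(self):
        cfg_s = SynthConfig(seed=4, shape=(150, 150), driver_snr=0.0,
                            n_drivers=3,
                            class_proportions=(0.6, 0.4, 0, 0, 0, 0, 0))
        grid = gen_landscape(cfg_s)
        drivers = gen_drivers(grid, cfg_s).normalize()
        cfg = ANNConfig(sampling_rate=0.1, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_suitability_model(
                sample_training(grid, drivers, cfg), cfg
            )
        cube = predict_suitability(model, drivers, grid)
        mean_prob = cube.prob.mean(axis=0)
        np.testing.assert_allclose(mean_prob[:2], (0.6, 0.4), atol=0.05)

    def test_training_deterministic(self, noiseless_scene):
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=0.05, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = train_suitability_model(sample_training(grid, drivers, cfg), cfg)
            m2 = train_suitability_model(sample_training(grid, drivers, cfg), cfg)
        c1 = predict_suitability(m1, drivers, grid)
        c2 = predict_suitability(m2, drivers, grid)
        np.testing.assert_array_equal(c1.prob, c2.prob)

    def test_held_out_log_loss_beats_prior(self, noiseless_scene):
        """Parameter recovery: the net carries information beyond priors."""
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=0.06, seed=5)
        samples = sample_training(grid, drivers, cfg)
        assert len(samples.y) >= 800
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_suitability_model(samples, cfg)
        cube = predict_suitability(model, drivers, grid)
        idx = grid.class_indices()[grid.valid_mask]
        model_ll = -np.mean(np.log(cube.prob[np.arange(len(idx)), idx]))
        priors = np.clip(samples.priors, 1e-9, None)
        prior_ll = -np.mean(np.log(priors[idx]))
        assert model_ll < prior_ll


class TestSuitabilityRMSE:
    def test_exact_one_hot_is_zero(self):
        grid = LandCoverGrid(np.full((5, 5), 10))
        prob = np.zeros((25, 7))
        prob[:, 0] = 1.0
        cube = SuitabilityCube(prob=prob, valid=grid.valid_mask)
        assert suitability_rmse(cube, grid) == 0.0

    def test_uniform_cube_closed_form(self):
        rng = np.random.default_rng(0)
        from greenscape.grid import GLOBELAND30

        grid = LandCoverGrid(rng.choice(GLOBELAND30.codes, size=(10, 10)))
        cube = SuitabilityCube(prob=np.full((100, 7), 1 / 7),
                               valid=grid.valid_mask)
        expected = np.sqrt((6 * (1 / 7) ** 2 + (6 / 7) ** 2) / 7)
        assert suitability_rmse(cube, grid) == pytest.approx(expected)

    def test_trained_model_beats_uniform(self, noiseless_scene):
        grid, drivers = noiseless_scene
        cfg = ANNConfig(sampling_rate=0.05, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_suitability_model(
                sample_training(grid, drivers, cfg), cfg
            )
        cube = predict_suitability(model, drivers, grid)
        uniform = SuitabilityCube(
            prob=np.full_like(cube.prob, 1 / 7), valid=grid.valid_mask
        )
        assert suitability_rmse(cube, grid) < suitability_rmse(uniform, grid)
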