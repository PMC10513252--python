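"""Detector architecture, detection loss closed forms, gradient correctness
and the training loop contract."""

import numpy as np
import pytest

from retrodetect import schema as S
from retrodetect.network import (Detector, LossWeights, ModelConfig, TrainConfig,
                                 detection_loss, detection_loss_grad, train)

TINY = ModelConfig(window_len=500, cell_size=100, stem_channels=4, stem_kernel=10,
                   block_factors=(5, 2, 5, 2), block_kernel=3, dtype="float64")


def random_grids(rng, b=2, c=5):
    """A random valid truth grid and an arbitrary prediction grid."""
    truth = np.zeros((b, c, S.N_COORDS))
    for i in range(b):
        for cell in rng.choice(c, size=rng.integers(0, c), replace=False):
            truth[i, cell, S.IDX_PRESENCE] = 1.0
            truth[i, cell, S.IDX_START] = rng.random()
            truth[i, cell, S.IDX_LENGTH] = rng.random() * 0.99 + 0.01
            truth[i, cell, 3 + rng.integers(S.N_TYPES)] = 1.0
            truth[i, cell, 3 + S.N_TYPES + rng.integers(S.N_LINEAGES)] = 1.0
    pred = rng.random((b, c, S.N_COORDS))
    return pred, truth


class TestArchitecture:
    def test_default_output_is_500_cells_by_22(self):
        model = Detector(ModelConfig(), seed=0)
        x = np.zeros((1, 4, 50_000), dtype=np.float32)
        assert model.forward(x).shape == (1, 500, 22)

    def test_scaled_window_output(self):
        model = Detector(ModelConfig(window_len=5_000), seed=0)
        assert model.forward(np.zeros((1, 4, 5_000))).shape == (1, 50, 22)

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(window_len=50_001)

    def test_factor_product_must_equal_cell_size(self):
        with pytest.raises(ValueError):
            ModelConfig(block_factors=(5, 2, 5))

    def test_outputs_bounded_and_softmax_normalized(self, rng):
        model = Detector(TINY, seed=1)
        x = (rng.random((3, 4, 500)) < 0.25).astype(np.float64)
        y = model.forward(x)
        assert np.all(y[..., :3] >= 0) and np.all(y[..., :3] <= 1)
        assert np.allclose(y[..., S.TYPE_SLICE].sum(-1), 1.0)
        assert np.allclose(y[..., S.LINEAGE_SLICE].sum(-1), 1.0)

    def test_save_load_round_trip(self, tmp_path, rng):
        model = Detector(TINY, seed=2)
        x = (rng.random((2, 4, 500)) < 0.25).astype(np.float64)
        y0 = model.predict(x)
        model.save(tmp_path / "m")
        back = Detector.load(tmp_path / "m")
        assert np.array_equal(back.predict(x), y0)


class TestDetectionLoss:
    def test_identical_grids_zero_loss(self, rng):
        _, truth = random_grids(rng)
        assert detection_loss(truth, truth) == 0.0

    def test_false_presence_in_background_cell_costs_lambda_nonobj(self):
        truth = np.zeros((1, 500, S.N_COORDS))
        pred = truth.copy()
        pred[0, 7, S.IDX_PRESENCE] = 1.0
        assert detection_loss(pred, truth) == pytest.approx(0.06)

    def test_object_cell_coordinate_errors(self):
        truth = np.zeros((1, 5, S.N_COORDS))
        truth[0, 2, S.IDX_PRESENCE] = 1.0
        truth[0, 2, S.IDX_START] = 0.5
        truth[0, 2, S.IDX_LENGTH] = 0.5
        truth[0, 2, 3] = 1.0
        truth[0, 2, 9] = 1.0
        pred = truth.copy()
        pred[0, 2, S.IDX_PRESENCE] -= 0.2
        pred[0, 2, S.IDX_START] += 0.1
        pred[0, 2, S.IDX_LENGTH] -= 0.1
        assert detection_loss(pred, truth) == pytest.approx(0.04 + 0.01 + 0.01)

    def test_background_xwc_unconstrained(self, rng):
        """Start/length/class coordinates of background cells never count."""
        truth = np.zeros((1, 5, S.N_COORDS))
        pred = truth.copy()
        pred[0, :, 1:] = rng.random((5, S.N_COORDS - 1))
        assert detection_loss(pred, truth) == 0.0

    def test_batch_mean_semantics(self):
        truth = np.zeros((2, 10, S.N_COORDS))
        pred = truth.copy()
        pred[0, 0, S.IDX_PRESENCE] = 1.0  # only sample 0 has an error
        assert detection_loss(pred, truth) == pytest.approx(0.06 / 2)

    def test_loss_nonnegative_property(self, rng):
        for _ in range(50):
            pred, truth = random_grids(rng)
            assert detection_loss(pred, truth) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detection_loss(np.zeros((1, 5, 22)), np.zeros((1, 6, 22)))

    def test_grad_matches_finite_differences(self, rng):
        pred, truth = random_grids(rng, b=2, c=4)
        w = LossWeights(lambda_obj=1.0, lambda_nonobj=0.06)
        grad = detection_loss_grad(pred, truth, w)
        eps = 1e-6
        for _ in range(30):
            i = tuple(rng.integers(s) for s in pred.shape)
            pp, pm = pred.copy(), pred.copy()
            pp[i] += eps
            pm[i] -= eps
            fd = (detection_loss(pp, truth, w) - detection_loss(pm, truth, w)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestNetworkGradient:
    def test_backprop_matches_finite_differences(self, rng):
        """End-to-end parameter gradients agree with central differences to
        1e-4 relative on a tiny float64 model."""
        model = Detector(TINY, seed=0)
        x = (rng.random((2, 4, 500)) < 0.25).astype(np.float64)
        _, truth = random_grids(rng, b=2, c=5)
        pred = model.forward(x, train=True)
        model.zero_grad()
        model.backward(detection_loss_grad(pred, truth))
        eps = 1e-6
        for p in model.parameters():
            flat, gflat = p.value.reshape(-1), p.grad.reshape(-1)
            for i in np.linspace(0, flat.size - 1, min(3, flat.size)).astype(int):
                old = flat[i]
                flat[i] = old + eps
                lp = detection_loss(model.forward(x, train=True), truth)
                flat[i] = old - eps
                lm = detection_loss(model.forward(x, train=True), truth)
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(fd, rel=1e-4, abs=1e-7), p.name


class TestTraining:
    def _toy_data(self, rng, n=16, window=500):
        x = (rng.random((n, 4, window)) < 0.25).astype(np.float32)
        y = np.zeros((n, window // 100, S.N_COORDS), dtype=np.float32)
        y[:, 1, S.IDX_PRESENCE] = 1.0
        y[:, 1, S.IDX_LENGTH] = 0.5
        y[:, 1, 3] = 1.0
        y[:, 1, 9] = 1.0
        return x, y

    def test_history_length_equals_epochs(self, rng):
        x, y = self._toy_data(rng)
        model = Detector(TINY, seed=0)
        _, hist = train(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=0))
        assert len(hist.train_loss) == 3 and len(hist.val_loss) == 3

    def test_same_seed_identical_histories(self, rng):
        x, y = self._toy_data(rng)
        hists = []
        for _ in range(2):
            model = Detector(TINY, seed=0)
            _, h = train(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=0))
            hists.append((h.train_loss, h.val_loss))
        assert hists[0] == hists[1]

    def test_loss_decreases_on_learnable_toy(self, rng):
        x, y = self._toy_data(rng, n=24)
        model = Detector(TINY, seed=1)
        _, hist = train(model, x, y,
                        TrainConfig(epochs=10, batch_size=8, learning_rate=0.005, seed=1))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_empty_dataset_rejected(self):
        model = Detector(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 4, 500)), np.zeros((0, 5, 22)), TrainConfig(epochs=1))

    def test_infeasible_split_rejected(self, rng):
        x, y = self._toy_data(rng, n=2)  # validation partition rounds to 0
        model = Detector(TINY, seed=0)
        with pytest.raises(ValueError, match="split"):
            train(model, x, y, TrainConfig(epochs=1))

    def test_invalid_split_sum_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split=(0.8, 0.1, 0.2))
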