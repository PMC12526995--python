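"""Regression and CNN estimators."""

import numpy as np
import pytest

from mdcpr.cnn import CnnSpec, TrainConfig, build_cnn, evaluate_cnn, train_cnn
from mdcpr.polyreg import fit_polyreg, predict_polyreg


class TestPolyreg:
    def test_interpolating_parabola_exact(self):
        m = fit_polyreg([0.0, 1.0, 2.0], [1.0, 2.0, 5.0])
        assert np.allclose(m.coefficients_raw, [1.0, 0.0, 1.0], atol=1e-9)
        assert predict_polyreg(m, 2.0) == pytest.approx(5.0, abs=1e-9)
        assert predict_polyreg(m, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_target(self):
        m = fit_polyreg([1.0, 2.0, 3.0, 4.0], [3.3] * 4)
        assert np.allclose(m.coefficients_raw, [3.3, 0.0, 0.0], atol=1e-10)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(80, 250, 200)
        y = 0.5 + 0.02 * x + 1e-4 * x**2 + rng.normal(0, 0.1, 200)
        m = fit_polyreg(x, y)
        # independent oracle: raw-basis pseudoinverse solve
        X = np.vander(x, 3, increasing=True)
        w_oracle = np.linalg.pinv(X) @ y
        assert np.allclose(m.coefficients_raw, w_oracle, atol=1e-10)
        grid = np.linspace(80, 250, 50)
        assert np.allclose(predict_polyreg(m, grid), np.vander(grid, 3, True) @ w_oracle,
                           atol=1e-10)

    def test_normal_equation_residual(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 60)
        y = rng.normal(2 + x, 0.5)
        m = fit_polyreg(x, y)
        z = (x - m.x_mean) / m.x_std
        X = np.vander(z, 3, increasing=True)
        resid = X.T @ (X @ m.weights - y)
        assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(X.T @ y)
        # training MSE matches the cost at the solution
        assert m.training_mse == pytest.approx(np.mean((X @ m.weights - y) ** 2))

    def test_monotone_prediction_on_monotone_data(self):
        # deeper compressions produce higher peak Doppler; the fitted map
        # must be increasing over the observed range
        rng = np.random.default_rng(5)
        depth = rng.uniform(3, 6, 300)
        fmax = 27.0 * depth + rng.normal(0, 3.0, 300)
        m = fit_polyreg(fmax, depth)
        grid = np.linspace(fmax.min(), fmax.max(), 100)
        assert np.all(np.diff(predict_polyreg(m, grid)) > 0)

    def test_rank_deficiency_named(self):
        with pytest.raises(ValueError, match="rank deficient"):
            fit_polyreg([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestCnnBuild:
    def test_parameter_count_64x64(self):
        model = build_cnn(seed=0)
        assert model.n_params == 283_329

    def test_parameter_count_by_layer(self):
        model = build_cnn(seed=0)
        conv_params = [l.n_params for l in model.layers if type(l).__name__ == "Conv2D"]
        assert conv_params == [80, 2336, 9248, 9248]
        bn_params = sum(l.n_params for l in model.layers if type(l).__name__ == "BatchNorm2D")
        assert bn_params == 208
        dense_params = [l.n_params for l in model.layers if type(l).__name__ == "Dense"]
        assert dense_params == [262_176, 33]

    def test_forward_on_zero_image_finite_scalar(self):
        model = build_cnn(seed=1)
        out = model.predict(np.zeros((1, 1, 64, 64)))
        assert out.shape == (1,)
        assert np.isfinite(out[0])

    def test_build_determinism(self):
        a = build_cnn(seed=3)
        b = build_cnn(seed=3)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_input_not_divisible_by_four_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            CnnSpec(input_hw=(62, 62))

    def test_gradients_match_numerical(self):
        spec = CnnSpec(input_hw=(8, 8), conv_filters=(2, 3, 3, 3), fc_width=4)
        model = build_cnn(spec, seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 1, 8, 8))
        y = np.array([1.0, 2.0, 3.0])

        def loss():
            return float(np.mean((model.forward(x, train=True) - y) ** 2))

        pred = model.forward(x, train=True)
        model.backward(2 * (pred - y) / len(y))
        eps = 1e-6
        checks = [(0, (1, 0, 2, 1)), (4, (2, 1, 0, 0)), (15, (5, 2)), (16, (3, 0))]
        for li, idx in checks:
            layer = model.layers[li]
            g = layer.grads[0][idx]
            w0 = layer.params[0][idx]
            layer.params[0][idx] = w0 + eps
            lp = loss()
            layer.params[0][idx] = w0 - eps
            lm = loss()
            layer.params[0][idx] = w0
            assert g == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-7)


class TestCnnTraining:
    @staticmethod
    def small_data(n=48, seed=0):
        # images whose mean intensity encodes the label
        rng = np.random.default_rng(seed)
        labels = rng.choice([3.0, 4.0, 5.0, 6.0], size=n)
        imgs = np.clip(
            labels[:, None, None, None] / 6.0
            + 0.05 * rng.standard_normal((n, 1, 16, 16)),
            0.0,
            1.0,
        )
        return imgs, labels

    @pytest.fixture()
    def small_spec(self):
        return CnnSpec(input_hw=(16, 16))

    def test_constant_labels_converge_to_constant(self, small_spec):
        # degenerate regression: identical inputs, all labels equal
        imgs = np.full((40, 1, 16, 16), 0.5)
        labels = np.full(40, 5.0)
        model = build_cnn(small_spec, seed=2)
        train_cnn(model, imgs, labels,
                  TrainConfig(learning_rate=1e-3, max_epochs=60, patience=60, seed=2))
        pred = model.predict(imgs)
        assert np.all(np.abs(pred - 5.0) < 0.1)

    def test_training_determinism(self, small_spec):
        imgs, labels = self.small_data()
        cfg = TrainConfig(max_epochs=5, patience=5, seed=9)
        h1 = train_cnn(build_cnn(small_spec, seed=9), imgs, labels, cfg)
        h2 = train_cnn(build_cnn(small_spec, seed=9), imgs, labels, cfg)
        assert h1.equals(h2)

    def test_early_stopping_returns_best_epoch_weights(self, small_spec):
        imgs, labels = self.small_data()
        model = build_cnn(small_spec, seed=4)
        x_val, y_val = self.small_data(n=16, seed=5)
        hist = train_cnn(
            model, imgs, labels,
            TrainConfig(max_epochs=25, patience=3, seed=4),
            validation=(x_val, y_val),
        )
        best = hist.attrs["best_epoch"]
        assert hist["val_loss"].iloc[best] == hist["val_loss"].min()
        # the restored weights reproduce the best validation loss
        val_loss = float(np.mean((model.predict(x_val) - y_val) ** 2))
        assert val_loss == pytest.approx(hist.attrs["best_val_loss"], rel=1e-9)
        # stopped before max_epochs or exhausted them; never after patience run-out
        after_best = hist["epoch"].iloc[-1] - best
        assert after_best <= 3 or len(hist) == 25

    def test_non_finite_loss_aborts(self, small_spec):
        imgs, labels = self.small_data()
        model = build_cnn(small_spec, seed=0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            train_cnn(model, imgs, labels * 1e6,
                      TrainConfig(learning_rate=10.0, max_epochs=3, patience=3, seed=0))

    def test_empty_inputs_rejected(self, small_spec):
        model = build_cnn(small_spec, seed=0)
        with pytest.raises(ValueError):
            train_cnn(model, np.zeros((0, 1, 16, 16)), np.zeros(0))


class TestEvaluateCnn:
    def test_perfect_and_constant_predictors(self, monkeypatch):
        model = build_cnn(CnnSpec(input_hw=(16, 16)), seed=0)
        labels = np.array([3.0, 4.0, 5.0, 6.0] * 4)
        imgs = np.zeros((16, 1, 16, 16))
        monkeypatch.setattr(model, "predict", lambda im: labels)
        assert evaluate_cnn(model, imgs, labels) == 0.0
        monkeypatch.setattr(model, "predict", lambda im: np.full(16, 4.5))
        assert evaluate_cnn(model, imgs, labels) == pytest.approx(np.sqrt(1.25))

    def test_empty_test_set_rejected(self):
        model = build_cnn(CnnSpec(input_hw=(16, 16)), seed=0)
        with pytest.raises(ValueError):
            evaluate_cnn(model, np.zeros((0, 1, 16, 16)), np.zeros(0))
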