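import numpy as np
import pytest

from amda.augmentation import (
    AugmentationConfig,
    NumericError,
    adversarial_perturb,
    amplify,
    mixup,
)
from amda.eeg_io import ValidationError, WindowSet
from amda.model import build, train


class LogisticModel:
    """Single-layer logistic oracle: logit = w.x + b, BCE loss.

    dJ/dx = (sigmoid(logit) - y) * w / n  (mean loss over the batch).
    """

    trained = True

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=np.float64)
        self.b = float(b)

    def logit(self, x):
        return x.reshape(len(x), -1) @ self.w.reshape(-1) + self.b

    def loss(self, x, y):
        z = self.logit(np.atleast_2d(x))
        y = np.atleast_1d(np.asarray(y, dtype=np.float64))
        return float(np.mean(np.logaddexp(0, z) - y * z))

    def input_gradient(self, x, y):
        x = np.atleast_2d(x)
        y = np.atleast_1d(np.asarray(y, dtype=np.float64))
        z = self.logit(x)
        err = 1 / (1 + np.exp(-z)) - y
        return (err[:, None] * self.w[None, :] / len(x)).reshape(x.shape)


def make_ws(n=20, channels=2, samples=16, seed=0):
    rng = np.random.default_rng(seed)
    return WindowSet(
        windows=rng.standard_normal((n, channels, samples)),
        labels=(np.arange(n) % 2),
        sources=[("p0", float(i)) for i in range(n)],
        window_s=1.0,
    )


# ----------------------------------------------------------- adversarial


def test_zero_budget_is_identity():
    model = LogisticModel([1.0, -2.0])
    x = np.array([[3.0, 4.0]])
    np.testing.assert_array_equal(adversarial_perturb(model, x, [1], eps=0.0), x)


def test_logistic_closed_form_oracle():
    # w = [1, -2], b = 0, x = [0, 0], y = 1, eps = 0.1:
    # sign(dJ/dx) = sign((sigma(0) - 1) * w) = [-1, +1]
    model = LogisticModel([1.0, -2.0])
    x = np.array([[0.0, 0.0]])
    x_adv = adversarial_perturb(model, x, [1.0], eps=0.1)
    np.testing.assert_allclose(x_adv, [[-0.1, 0.1]], atol=1e-12)
    assert abs(model.logit(x_adv)[0] - (-0.3)) < 1e-12
    assert abs(model.loss(x, [1.0]) - 0.6931471805599453) < 1e-10
    assert abs(model.loss(x_adv, [1.0]) - np.log(1 + np.exp(0.3))) < 1e-10
    assert abs(model.loss(x_adv, [1.0]) - 0.8543552) < 1e-6


@pytest.mark.parametrize("eps", [0.05, 0.1, 0.2])
def test_linear_logit_drop_is_eps_times_l1_norm(eps, rng):
    w = rng.standard_normal(6)
    model = LogisticModel(w, b=0.3)
    x = rng.standard_normal((4, 6))
    y = np.ones(4)
    x_adv = adversarial_perturb(model, x, y, eps=eps)
    drop = model.logit(x) - model.logit(x_adv)
    np.testing.assert_allclose(drop, eps * np.abs(w).sum(), atol=1e-6)
    assert model.loss(x_adv, y) > model.loss(x, y)


def test_full_network_loss_ascent_small_eps(separable_windows, tiny_model_cfg):
    ws = separable_windows(n=40)
    model = build(tiny_model_cfg, 2, 32)
    train(model, ws, tiny_model_cfg)
    x, y = ws.windows, ws.labels.astype(float)
    x_adv = adversarial_perturb(model, x, y, eps=0.01)
    increased = 0
    for i in range(len(x)):
        before = model.loss(x[i : i + 1], y[i : i + 1])
        after = model.loss(x_adv[i : i + 1], y[i : i + 1])
        increased += after >= before
    assert increased / len(x) >= 0.95


def test_eps_ball_containment_exact(separable_windows, tiny_model_cfg):
    ws = separable_windows(n=24)
    model = build(tiny_model_cfg, 2, 32)
    train(model, ws, tiny_model_cfg)
    for steps in (1, 4):
        x_adv = adversarial_perturb(model, ws.windows, ws.labels, eps=0.1, steps=steps)
        assert np.max(np.abs(x_adv - ws.windows)) <= 0.1 + 1e-15


def test_nonfinite_gradient_raises():
    class BadModel:
        trained = True

        def input_gradient(self, x, y):
            g = np.zeros_like(x)
            g.flat[0] = np.nan
            return g

    with pytest.raises(NumericError):
        adversarial_perturb(BadModel(), np.zeros((1, 4)), [1], eps=0.1)


# ----------------------------------------------------------------- mixup


def test_mixup_identity():
    x_i, x_j = np.array([1.0, 2.0]), np.array([5.0, -1.0])
    out_x, out_y = mixup(x_i, 1, x_j, 0, lam=1.0)
    np.testing.assert_array_equal(out_x, x_i)
    assert out_y == 1.0


def test_mixup_midpoint():
    out_x, out_y = mixup(np.array([2.0]), 1, np.array([4.0]), 0, lam=0.5)
    np.testing.assert_allclose(out_x, [3.0])
    assert out_y == 0.5


def test_mixup_convexity(rng):
    x_i = rng.standard_normal(8)
    x_j = rng.standard_normal(8)
    for lam in np.linspace(0, 1, 11):
        out_x, out_y = mixup(x_i, 1, x_j, 0, lam=float(lam))
        assert np.all(out_x >= np.minimum(x_i, x_j) - 1e-12)
        assert np.all(out_x <= np.maximum(x_i, x_j) + 1e-12)
        assert 0.0 <= out_y <= 1.0


def test_mixup_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        mixup(np.zeros(3), 1, np.zeros(4), 0, lam=0.5)


# --------------------------------------------------------------- amplify


def trained_tiny(separable_windows, tiny_model_cfg, n=20):
    ws = separable_windows(n=n)
    model = build(tiny_model_cfg, 2, 32)
    train(model, ws, tiny_model_cfg)
    return ws, model


@pytest.mark.parametrize("n", [0, 1, 2, 3])
def test_count_law(n, separable_windows, tiny_model_cfg):
    ws, model = trained_tiny(separable_windows, tiny_model_cfg)
    cfg = AugmentationConfig(multiplier=n, seed=3)
    out = amplify(ws, model, cfg)
    assert len(out) == (1 + n) * len(ws)


def test_multiplier_zero_identity(separable_windows):
    ws = separable_windows(n=10)
    out = amplify(ws, None, AugmentationConfig(multiplier=0))
    np.testing.assert_array_equal(out.windows, ws.windows)
    np.testing.assert_array_equal(out.labels, ws.labels.astype(float))
    assert all(o == "original" for o in out.origin)


def test_untrained_model_rejected(separable_windows, tiny_model_cfg):
    ws = separable_windows(n=10)
    model = build(tiny_model_cfg, 2, 32)  # never trained
    with pytest.raises(ValidationError):
        amplify(ws, model, AugmentationConfig(multiplier=1))


def test_adversarial_members_stay_in_eps_ball(separable_windows, tiny_model_cfg):
    ws, model = trained_tiny(separable_windows, tiny_model_cfg)
    cfg = AugmentationConfig(multiplier=2, epsilon=0.07, seed=5)
    out = amplify(ws, model, cfg)
    for w, origin, (src_i, _, _) in zip(out.windows, out.origin, out.provenance):
        if origin == "adversarial":
            assert np.max(np.abs(w - ws.windows[src_i])) <= cfg.epsilon + 1e-15


def test_mixup_members_match_recorded_combination(separable_windows, tiny_model_cfg):
    ws, model = trained_tiny(separable_windows, tiny_model_cfg)
    out = amplify(ws, model, AugmentationConfig(multiplier=1, seed=8))
    y = ws.labels.astype(float)
    n_mix = 0
    for w, label, origin, (i, j, lam) in zip(out.windows, out.labels, out.origin, out.provenance):
        if origin == "mixup":
            n_mix += 1
            np.testing.assert_allclose(w, lam * ws.windows[i] + (1 - lam) * ws.windows[j], atol=1e-12)
            assert abs(label - (lam * y[i] + (1 - lam) * y[j])) < 1e-12
            assert 0.0 <= label <= 1.0
    assert n_mix == round(0.5 * len(ws))


def test_amplify_bit_reproducible(separable_windows, tiny_model_cfg):
    ws, model = trained_tiny(separable_windows, tiny_model_cfg)
    cfg = AugmentationConfig(multiplier=3, seed=42)
    a = amplify(ws, model, cfg)
    b = amplify(ws, model, cfg)
    np.testing.assert_array_equal(a.windows, b.windows)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(np.array(a.provenance), np.array(b.provenance))


def test_augmented_set_serialization(tmp_path, separable_windows, tiny_model_cfg):
    ws, model = trained_tiny(separable_windows, tiny_model_cfg)
    out = amplify(ws, model, AugmentationConfig(multiplier=1, seed=0))
    out.save(tmp_path / "aug.npz", tmp_path / "prov.csv")
    with np.load(tmp_path / "aug.npz") as data:
        np.testing.assert_array_equal(data["windows"], out.windows)
        np.testing.assert_array_equal(data["labels"], out.labels)
    lines = (tmp_path / "prov.csv").read_text().strip().splitlines()
    assert lines[0] == "origin,src_i,src_j,lam,label"
    assert len(lines) == 1 + len(out)


def test_config_validation():
    with pytest.raises(ValidationError):
        AugmentationConfig(epsilon=-0.1).validate()
    with pytest.raises(ValidationError):
        AugmentationConfig(mix_ratio=1.5).validate()
    with pytest.raises(ValidationError):
        AugmentationConfig(mixup_alpha=0.0).validate()
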