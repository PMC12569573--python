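"""Segmentation losses against independent oracles."""

import numpy as np
import pytest

from lvnckit.nn.losses import (
    lovasz_softmax_loss,
    softmax_backward,
    total_loss,
    weighted_bce_loss,
)


def one_hot_probs(labels, n_classes=4, confidence=1.0):
    b, h, w = labels.shape
    probs = np.full((b, n_classes, h, w), (1 - confidence) / (n_classes - 1))
    for c in range(n_classes):
        probs[:, c][labels == c] = confidence
    return probs


def lovasz_oracle(probs, labels):
    """Literal Lovász extension: evaluate the Jaccard set function on the
    growing set of sorted errors, class by class, and average over classes
    present.  Independent of the vectorised implementation."""
    losses = []
    flat_labels = labels.reshape(-1)
    for c in range(probs.shape[1]):
        fg = set(np.nonzero(flat_labels == c)[0].tolist())
        if not fg:
            continue
        p = probs[:, c].reshape(-1)
        errors = [abs((1.0 if i in fg else 0.0) - p[i]) for i in range(len(p))]
        order = sorted(range(len(p)), key=lambda i: -errors[i])

        def jaccard_loss_of_error_set(err_set):
            # prediction = ground truth with the pixels in err_set flipped
            pred = fg.symmetric_difference(err_set)
            inter = len(fg & pred)
            union = len(fg | pred)
            return 1.0 - inter / union if union else 0.0

        loss = 0.0
        prev = jaccard_loss_of_error_set(set())
        grown: set = set()
        for i in order:
            grown.add(i)
            cur = jaccard_loss_of_error_set(grown)
            loss += errors[i] * (cur - prev)
            prev = cur
        losses.append(loss)
    return float(np.mean(losses)) if losses else 0.0


class TestLovaszSoftmax:
    def test_perfect_one_hot_prediction_is_zero(self, rng):
        labels = rng.integers(0, 4, (1, 4, 4))
        loss, grad = lovasz_softmax_loss(one_hot_probs(labels), labels)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_fully_wrong_single_class_image_is_one(self):
        labels = np.full((1, 3, 3), 2)
        probs = one_hot_probs(np.full((1, 3, 3), 1))  # confidently class 1
        loss, _ = lovasz_softmax_loss(probs, labels)
        assert loss == pytest.approx(1.0)

    def test_matches_set_function_oracle_on_random_fields(self, rng):
        for _ in range(25):
            labels = rng.integers(0, 4, (1, 3, 3))
            raw = rng.random((1, 4, 3, 3))
            probs = raw / raw.sum(axis=1, keepdims=True)
            loss, _ = lovasz_softmax_loss(probs, labels)
            assert loss == pytest.approx(lovasz_oracle(probs, labels), abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        labels = rng.integers(0, 4, (1, 3, 3))
        raw = rng.random((1, 4, 3, 3)) + 0.1
        probs = raw / raw.sum(axis=1, keepdims=True)
        _, grad = lovasz_softmax_loss(probs, labels)
        eps = 1e-7
        for idx in [(0, 0, 1, 1), (0, 2, 0, 2), (0, 3, 2, 1)]:
            p_plus = probs.copy()
            p_plus[idx] += eps
            p_minus = probs.copy()
            p_minus[idx] -= eps
            num = (
                lovasz_softmax_loss(p_plus, labels)[0]
                - lovasz_softmax_loss(p_minus, labels)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-5)


class TestWeightedBce:
    def test_near_perfect_prediction_vanishes(self, rng):
        labels = rng.integers(0, 4, (1, 4, 4))
        probs = one_hot_probs(labels, confidence=1 - 1e-7)
        loss, _ = weighted_bce_loss(probs, labels)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_unit_weights_equal_plain_bce(self, rng):
        labels = rng.integers(0, 4, (1, 4, 4))
        raw = rng.random((1, 4, 4, 4)) + 0.05
        probs = raw / raw.sum(axis=1, keepdims=True)
        loss_w, _ = weighted_bce_loss(probs, labels, np.ones(4))
        p = np.clip(probs, 1e-7, 1 - 1e-7)
        targets = np.stack([(labels == c) for c in range(4)], axis=1)
        plain = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).mean()
        assert loss_w == pytest.approx(plain)

    def test_single_pixel_hand_value(self):
        # one pixel, true class 3, weights (1, 1, 1, 2):
        # probs (0.1, 0.2, 0.3, 0.4) ->
        # 2 * [ -ln(1-.1) - ln(1-.2) - ln(1-.3) - ln(.4) ] / 4
        labels = np.array([[[3]]])
        probs = np.array([0.1, 0.2, 0.3, 0.4]).reshape(1, 4, 1, 1)
        loss, _ = weighted_bce_loss(probs, labels, np.array([1, 1, 1, 2.0]))
        expected = (
            2.0
            * (
                -np.log(0.9) - np.log(0.8) - np.log(0.7) - np.log(0.4)
            )
            / 4.0
        )
        assert loss == pytest.approx(expected, rel=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        labels = rng.integers(0, 4, (1, 3, 3))
        raw = rng.random((1, 4, 3, 3)) + 0.1
        probs = raw / raw.sum(axis=1, keepdims=True)
        weights = np.array([0.5, 1.0, 1.5, 2.0])
        _, grad = weighted_bce_loss(probs, labels, weights)
        eps = 1e-7
        for idx in [(0, 1, 0, 0), (0, 3, 1, 2)]:
            p_plus = probs.copy()
            p_plus[idx] += eps
            p_minus = probs.copy()
            p_minus[idx] -= eps
            num = (
                weighted_bce_loss(p_plus, labels, weights)[0]
                - weighted_bce_loss(p_minus, labels, weights)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4)


class TestTotalLoss:
    def test_sum_of_components(self, rng):
        labels = rng.integers(0, 4, (2, 4, 4))
        raw = rng.random((2, 4, 4, 4)) + 0.05
        probs = raw / raw.sum(axis=1, keepdims=True)
        ll, dl = total_loss(probs, labels)
        l1, g1 = lovasz_softmax_loss(probs, labels)
        l2, g2 = weighted_bce_loss(probs, labels)
        assert ll == pytest.approx(l1 + l2)
        assert np.allclose(dl, g1 + g2)

    def test_perfect_prediction_vanishes(self, rng):
        labels = rng.integers(0, 4, (1, 4, 4))
        probs = one_hot_probs(labels, confidence=1 - 1e-7)
        loss, _ = total_loss(probs, labels)
        assert loss == pytest.approx(0.0, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.zeros((1, 4, 4, 4)), np.zeros((1, 5, 5), dtype=int))


class TestSoftmaxBackward:
    def test_matches_jacobian_product(self, rng):
        logits = rng.normal(size=(1, 4, 2, 2))
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        dprobs = rng.normal(size=probs.shape)
        dlogits = softmax_backward(probs, dprobs)
        # Jacobian of softmax at one pixel: diag(p) - p p^T
        for i in range(2):
            for j in range(2):
                p = probs[0, :, i, j]
                jac = np.diag(p) - np.outer(p, p)
                assert np.allclose(dlogits[0, :, i, j], jac @ dprobs[0, :, i, j])
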