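"""Capsule mathematics: squash, routing, lengths, margin loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capgan as cg
from capgan.capsule import MarginLossParams

from _oracles import routing_reference, squash_reference


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(cg.squash(np.zeros(2)), 0.0)

    def test_unit_vector_norm_half(self):
        v = cg.squash(np.array([1.0, 0.0]))
        assert np.allclose(v, [0.5, 0.0], atol=1e-12)

    def test_three_four_case(self):
        v = cg.squash(np.array([3.0, 4.0]))
        assert np.allclose(v, [75 / 130, 100 / 130], atol=1e-9)
        assert np.isclose(np.linalg.norm(v), 25 / 26, atol=1e-9)

    def test_norm_monotone_and_bounded(self):
        direction = np.array([1.0, 2.0]) / np.sqrt(5.0)
        norms = [np.linalg.norm(cg.squash(direction * t)) for t in np.logspace(-2, 3, 40)]
        assert all(b > a for a, b in zip(norms, norms[1:]))
        assert all(n < 1.0 for n in norms)
        assert norms[-1] > 0.999999  # t = 1e3

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cg.squash(np.array([np.nan, 1.0]))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_reference(self, vals):
        s = np.array(vals)
        assert np.allclose(cg.squash(s), squash_reference(s), atol=1e-9)


class TestLeakyRelu:
    @pytest.mark.parametrize("x,expected", [(2.0, 2.0), (0.0, 0.0), (-1.0, -0.2)])
    def test_multiplicative_convention(self, x, expected):
        assert np.isclose(cg.leaky_relu(np.array(x), 0.2), expected)

    def test_literal_mode_divides(self):
        assert np.isclose(cg.leaky_relu(np.array(-1.0), 0.2, mode="literal"), -5.0)

    def test_bad_slope_rejected(self):
        with pytest.raises(ValueError):
            cg.leaky_relu(np.array(1.0), slope=0.0)
        with pytest.raises(ValueError):
            cg.leaky_relu(np.array(1.0), slope=-0.1)


class TestRoutingSoftmax:
    def test_uniform_at_zero_logits(self):
        assert np.allclose(cg.routing_softmax(np.zeros(2)), [0.5, 0.5])

    def test_log_two_case(self):
        assert np.allclose(cg.routing_softmax(np.array([np.log(2.0), 0.0])), [2 / 3, 1 / 3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cg.routing_softmax(np.array([]))

    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_probability_vector(self, logits):
        c = cg.routing_softmax(np.array(logits))
        assert np.all(c >= 0)
        assert np.isclose(c.sum(), 1.0, atol=1e-12)


class TestPredictVectors:
    def test_identity_transform(self, rng):
        u = rng.normal(size=(2, 3, 4))
        W = np.broadcast_to(np.eye(4), (3, 2, 4, 4)).copy()
        u_hat = cg.predict_vectors(u, W)
        for j in range(2):
            assert np.allclose(u_hat[:, :, j, :], u)

    def test_zero_input(self):
        W = np.random.default_rng(0).normal(size=(3, 2, 5, 4))
        u_hat = cg.predict_vectors(np.zeros((1, 3, 4)), W)
        assert np.allclose(u_hat, 0.0)

    def test_two_d_case(self):
        W = np.array([[1.0, 0.0], [0.0, 2.0]]).reshape(1, 1, 2, 2)
        u = np.array([1.0, 1.0]).reshape(1, 1, 2)
        assert np.allclose(cg.predict_vectors(u, W)[0, 0, 0], [1.0, 2.0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cg.predict_vectors(np.zeros((1, 3, 4)), np.zeros((3, 2, 5, 7)))


class TestDynamicRouting:
    def test_single_output_capsule_sums_inputs(self, rng):
        u_hat = rng.normal(size=(2, 5, 1, 3))
        v = cg.dynamic_routing(u_hat, r=3, activation="leaky_relu")
        expected = cg.leaky_relu(u_hat.sum(axis=1), 0.2)  # c == 1 when J = 1
        assert np.allclose(v, expected, atol=1e-10)

    def test_zero_predictions_give_zero(self):
        v = cg.dynamic_routing(np.zeros((1, 4, 2, 3)), r=2, activation="squash")
        assert np.allclose(v, 0.0)

    def test_requires_at_least_one_iteration(self):
        with pytest.raises(ValueError):
            cg.dynamic_routing(np.zeros((1, 2, 2, 2)), r=0)

    @pytest.mark.parametrize("activation", ["squash", "leaky_relu"])
    def test_matches_bruteforce_reference(self, activation):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n_in = rng.integers(1, 5)
            n_out = rng.integers(1, 5)
            d = rng.integers(1, 9)
            r = rng.integers(1, 5)
            u_hat = rng.normal(size=(n_in, n_out, d))
            ours = cg.dynamic_routing(u_hat[None], r=int(r), activation=activation)[0]
            ref = routing_reference(u_hat, int(r), activation)
            assert np.allclose(ours, ref, atol=1e-10)

    def test_coupling_state_is_probability(self, rng):
        u_hat = rng.normal(size=(1, 4, 3, 5))
        _, state = cg.dynamic_routing(u_hat, r=3, return_state=True)
        state.validate()
        assert np.allclose(state.c.sum(axis=-1), 1.0, atol=1e-6)


class TestCapsuleLength:
    def test_pythagorean(self):
        assert np.isclose(cg.capsule_length(np.array([3.0, 4.0])), 5.0, atol=1e-9)

    def test_zero(self):
        assert np.isclose(cg.capsule_length(np.zeros(4)), 0.0, atol=1e-8)

    def test_unit(self):
        assert np.isclose(cg.capsule_length(np.array([1.0, 0.0, 0.0])), 1.0, atol=1e-9)


class TestMarginLoss:
    def test_positive_class_inside_margin_is_free(self):
        assert np.isclose(cg.margin_loss(np.array([0.9]), np.array([1.0])), 0.0)

    def test_positive_class_short_vector(self):
        assert np.isclose(cg.margin_loss(np.array([0.5]), np.array([1.0])), 0.16, atol=1e-12)

    def test_negative_class_long_vector(self):
        assert np.isclose(cg.margin_loss(np.array([0.5]), np.array([0.0])), 0.08, atol=1e-12)

    def test_zero_iff_margins_satisfied(self, rng):
        params = MarginLossParams()
        lengths = np.array([0.95, 0.05])
        targets = np.array([1.0, 0.0])
        assert cg.margin_loss(lengths, targets, params) == 0.0
        # violate either margin -> strictly positive
        assert cg.margin_loss(np.array([0.89, 0.05]), targets, params) > 0
        assert cg.margin_loss(np.array([0.95, 0.11]), targets, params) > 0

    def test_default_params(self):
        p = MarginLossParams()
        assert (p.m_plus, p.m_minus, p.lam) == (0.9, 0.1, 0.5)
        with pytest.raises(ValueError):
            MarginLossParams(m_plus=1.5)
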