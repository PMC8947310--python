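"""Capsule mathematics: squash, routing, lengths, classification, loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tonguecaps.capsule import (
    CapsuleBank,
    MarginLossParams,
    PredictionTensor,
    TransformWeights,
    capsule_lengths,
    classify,
    coupling_from_logits,
    dynamic_routing,
    margin_loss,
    predict_vectors,
    squash,
)

from _reference import reference_routing, reference_squash


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(squash(np.zeros(4)), 0.0)

    @pytest.mark.parametrize("norm, expected", [(1.0, 0.5), (3.0, 0.9)])
    def test_closed_form_lengths(self, norm, expected):
        v = np.zeros(5)
        v[2] = norm
        assert np.linalg.norm(squash(v)) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(arrays(np.float64, 4, elements=st.floats(-50, 50)))
    def test_direction_preserved_and_length_bounded(self, v):
        out = squash(v)
        n = np.linalg.norm(v)
        assert np.linalg.norm(out) < 1.0
        if n > 1e-6:
            cos = np.dot(out, v) / (np.linalg.norm(out) * n)
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_length_strictly_increasing_in_input_norm(self):
        norms = np.linspace(0.1, 10, 50)
        out = [np.linalg.norm(squash(np.array([n, 0.0]))) for n in norms]
        assert (np.diff(out) > 0).all()

    def test_matches_scalar_reference(self, rng):
        for _ in range(50):
            v = rng.normal(size=rng.integers(1, 6))
            assert np.allclose(squash(v), reference_squash(v.tolist()), atol=1e-9)


class TestPredictVectors:
    def test_identity_weights_reproduce_inputs(self, rng):
        u = rng.normal(size=(3, 4))
        W = np.broadcast_to(np.eye(4), (3, 2, 4, 4)).copy()
        u_hat = predict_vectors(u, W)
        for j in range(2):
            assert np.allclose(u_hat[:, j], u)

    def test_zero_inputs_give_zero_predictions(self):
        W = np.ones((2, 3, 4, 5))
        assert not predict_vectors(np.zeros((2, 4)), W).any()

    def test_hand_worked_matrix_product(self):
        u = np.array([[1.0, 2.0]])
        W = np.array([[[[1.0, 0.0], [0.0, 2.0]]]])  # (1,1,2,2)
        assert np.allclose(predict_vectors(u, W)[0, 0], [1.0, 4.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_vectors(np.zeros((2, 3)), np.zeros((2, 1, 4, 4)))


class TestCouplings:
    def test_zero_logits_give_uniform(self):
        c = coupling_from_logits(np.zeros((3, 4)))
        assert np.allclose(c, 0.25)

    def test_hand_evaluated_softmax(self):
        c = coupling_from_logits(np.array([[np.log(2.0), 0.0]]))
        assert np.allclose(c, [2 / 3, 1 / 3])

    def test_shift_invariance(self, rng):
        b = rng.normal(size=(4, 5))
        assert np.allclose(coupling_from_logits(b), coupling_from_logits(b + 7.3))

    def test_rows_sum_to_one(self, rng):
        c = coupling_from_logits(rng.normal(size=(64, 7), scale=10))
        assert np.abs(c.sum(axis=-1) - 1.0).max() <= 1e-12


class TestDynamicRouting:
    def test_single_output_capsule_sums_predictions(self, rng):
        u_hat = rng.normal(size=(5, 1, 3))
        for r in (1, 2, 4):
            v, state = dynamic_routing(u_hat, r)
            assert np.allclose(state.c, 1.0)
            assert np.allclose(v[0], squash(u_hat[:, 0].sum(axis=0)), atol=1e-12)

    def test_one_iteration_closed_form(self, rng):
        u_hat = rng.normal(size=(4, 3, 2))
        v, _ = dynamic_routing(u_hat, 1)
        expected = np.stack([squash(u_hat[:, j].sum(axis=0) / 3.0) for j in range(3)])
        assert np.allclose(v, expected, atol=1e-12)

    def test_matches_straight_line_reference_on_random_instances(self, rng):
        worst = 0.0
        for _ in range(200):
            n_in = int(rng.integers(1, 9))
            n_out = int(rng.integers(1, 5))
            d = int(rng.integers(1, 5))
            r = int(rng.integers(1, 4))
            u_hat = rng.normal(size=(n_in, n_out, d))
            v, state = dynamic_routing(u_hat, r)
            ref_v, ref_b, ref_c = reference_routing(u_hat.tolist(), r)
            worst = max(worst, np.abs(v - np.array(ref_v)).max())
            worst = max(worst, np.abs(state.c - np.array(ref_c)).max())
        assert worst <= 1e-9

    def test_agreement_concentrates_couplings(self):
        # both inputs agree on capsule 0 and oppose each other on capsule 1
        shared = np.array([2.0, 0.0])
        u_hat = np.array(
            [[shared, [1.5, 0.5]], [shared, [-1.5, -0.5]]], dtype=float
        )  # (2, 2, 2)
        _, state = dynamic_routing(u_hat, 2)
        assert (state.c[:, 0] > 0.5).all()

    def test_couplings_normalised_every_round(self, rng):
        u_hat = rng.normal(size=(6, 4, 3), scale=5)
        for r in (1, 2, 3):
            _, state = dynamic_routing(u_hat, r)
            assert np.abs(state.c.sum(axis=-1) - 1.0).max() <= 1e-12

    def test_batched_agrees_with_per_sample(self, rng):
        u_hat = rng.normal(size=(3, 4, 2, 5))
        v_batch, _ = dynamic_routing(u_hat, 3)
        for k in range(3):
            v_k, _ = dynamic_routing(u_hat[k], 3)
            assert np.allclose(v_batch[k], v_k, atol=1e-12)

    def test_invalid_iterations_rejected(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((2, 2, 2)), 0)


class TestLengthsAndClassify:
    def test_lengths(self):
        v = np.array([[1.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
        assert np.allclose(capsule_lengths(v), [1.0, 5.0, 0.0])

    @pytest.mark.parametrize(
        "lengths, expected",
        [
            ((0.1, 0.9, 0.2, 0.05, 0.3), 1),
            ((0.2, 0.2, 0.8, 0.1, 0.1), 2),
            ((0.4, 0.4, 0.4), 0),  # tie -> lowest index
        ],
    )
    def test_argmax_with_tie_break(self, lengths, expected):
        assert classify(np.array(lengths)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([]))


class TestMarginLoss:
    def test_zero_exactly_at_margins(self):
        lengths = np.array([0.9, 0.1, 0.1, 0.1, 0.1])
        target = np.eye(5)[0]
        assert float(margin_loss(lengths, target)) == pytest.approx(0.0, abs=1e-12)

    def test_absent_correct_class_costs_squared_margin(self):
        lengths = np.array([0.0, 0.1, 0.1])
        assert float(margin_loss(lengths, np.eye(3)[0])) == pytest.approx(0.81)

    def test_overlong_wrong_class_contribution(self):
        # correct class at its margin; one wrong class at 0.6 -> 0.5*(0.5)^2
        lengths = np.array([0.9, 0.6])
        assert float(margin_loss(lengths, np.array([1.0, 0.0]))) == pytest.approx(0.125)

    def test_batch_reduction_is_mean_of_per_sample_sums(self, rng):
        lengths = rng.uniform(0, 1, size=(8, 5))
        targets = np.eye(5)[rng.integers(0, 5, 8)]
        batch = float(margin_loss(lengths, targets))
        singles = [float(margin_loss(lengths[i], targets[i])) for i in range(8)]
        assert batch == pytest.approx(np.mean(singles))

    def test_zero_iff_margins_satisfied(self, rng):
        params = MarginLossParams()
        for _ in range(200):
            lengths = rng.uniform(0, 1, size=5)
            target = np.eye(5)[rng.integers(0, 5)]
            loss = float(margin_loss(lengths, target, params))
            k = int(np.argmax(target))
            satisfied = lengths[k] >= params.m_plus and all(
                lengths[j] <= params.m_minus for j in range(5) if j != k
            )
            assert (loss == 0.0) == satisfied

    def test_cardinality_mismatch_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(np.zeros(4), np.zeros(5))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MarginLossParams(m_plus=0.1, m_minus=0.9)


class TestCapsuleBank:
    def test_output_role_enforces_unit_lengths(self):
        with pytest.raises(ValueError):
            CapsuleBank(np.full((2, 3), 2.0), role="output")
        bank = CapsuleBank(np.full((2, 3), 0.5), role="input")
        assert bank.count == 2 and bank.dimension == 3

    def test_typed_containers_flow_through_routing(self, rng):
        bank = CapsuleBank(rng.normal(size=(3, 4)))
        weights = TransformWeights(rng.normal(size=(3, 2, 4, 5)))
        u_hat = predict_vectors(bank, weights)
        v_typed, _ = dynamic_routing(PredictionTensor(u_hat), 2)
        v_raw, _ = dynamic_routing(u_hat, 2)
        assert np.array_equal(v_typed, v_raw)

    def test_non_finite_weights_rejected(self):
        with pytest.raises(ValueError):
            TransformWeights(np.full((1, 1, 2, 2), np.inf))
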