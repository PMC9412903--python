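import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhythmrec.core import Action, FeatureScaler, N_FEATURES
from rhythmrec.errors import DimensionMismatchError, EmptyBatchError
from rhythmrec.rl import (
    Experience,
    QPolicyModel,
    RLTrainConfig,
    epsilon_greedy_action,
    greedy_action,
    q_batch_update,
    q_predict,
    q_single_delta,
    rl_train,
    warm_start_from_sl,
)
from rhythmrec.sl import SLPolicyModel


def _e1():
    x = np.zeros(N_FEATURES)
    x[0] = 1.0
    return x


def _exp(x, action, reward):
    return Experience(x=x, action_taken=action, reward=reward)


@pytest.fixture
def zero_model(unit_scaler):
    return QPolicyModel.zeros(unit_scaler)


class TestQPredict:
    def test_zero_weights(self, zero_model):
        np.testing.assert_array_equal(q_predict(zero_model, _e1()), np.zeros(4))

    def test_intercept_only_dot_product(self, unit_scaler):
        V = np.zeros((4, 9))
        V[Action.AAM, 0] = -2.0
        model = QPolicyModel(V, unit_scaler)
        np.testing.assert_array_equal(q_predict(model, _e1()), [0, 0, -2, 0])

    def test_random_matches_hand_matrix_product(self, unit_scaler):
        rng = np.random.default_rng(3)
        for _ in range(20):
            V = rng.normal(size=(4, 9))
            x = rng.normal(size=9)
            model = QPolicyModel(V, unit_scaler)
            # brute-force oracle: explicit per-entry dot products
            expected = [sum(V[a, j] * x[j] for j in range(9)) for a in range(4)]
            np.testing.assert_allclose(q_predict(model, x), expected, rtol=1e-12)

    def test_dimension_mismatch(self, zero_model):
        with pytest.raises(DimensionMismatchError):
            q_predict(zero_model, np.ones(4))


class TestQSingleDelta:
    def test_zero_td_error_gives_zero_matrix(self, unit_scaler):
        V = np.zeros((4, 9))
        V[0, 0] = -2.0
        model = QPolicyModel(V, unit_scaler)
        delta = q_single_delta(model, _exp(_e1(), Action.RAC, -2.0), lr=0.01)
        np.testing.assert_array_equal(delta, np.zeros((4, 9)))

    def test_hand_computed_first_delta(self, zero_model):
        delta = q_single_delta(zero_model, _exp(_e1(), Action.RAC, -2.0), lr=0.01)
        assert delta[0, 0] == pytest.approx(-0.02)  # 0.01 * (-2 - 0) * 1
        delta[0, 0] = 0.0
        np.testing.assert_array_equal(delta, np.zeros((4, 9)))

    def test_only_taken_row_changes(self, unit_scaler):
        rng = np.random.default_rng(9)
        for _ in range(20):
            model = QPolicyModel(rng.normal(size=(4, 9)), unit_scaler)
            x = rng.normal(size=9)
            a = Action(int(rng.integers(4)))
            delta = q_single_delta(model, _exp(x, a, float(rng.normal())), lr=0.01)
            mask = np.ones(4, dtype=bool)
            mask[int(a)] = False
            assert np.all(delta[mask] == 0.0)

    def test_geometric_convergence_closed_form(self, zero_model):
        # repeated single updates on intercept-only x: Q_n = r(1 - (1-lr)^n)
        lr, r, n = 0.05, -3.0, 40
        model = zero_model
        for _ in range(n):
            delta = q_single_delta(model, _exp(_e1(), Action.EXC, r), lr)
            model = QPolicyModel(model.weights + delta, model.scaler)
        expected = r * (1 - (1 - lr) ** n)
        assert q_predict(model, _e1())[Action.EXC] == pytest.approx(expected, rel=1e-12)

    def test_no_mutation(self, zero_model):
        q_single_delta(zero_model, _exp(_e1(), Action.RAC, -1.0), lr=0.01)
        assert np.all(zero_model.weights == 0)


def _oracle_batch_mean(model, batch, lr):
    """Independent oracle: per-experience deltas at fixed pre-batch weights,
    computed with plain Python loops, then averaged."""
    agg = np.zeros((4, 9))
    for e in batch:
        q = sum(model.weights[int(e.action_taken), j] * e.x[j] for j in range(9))
        for j in range(9):
            agg[int(e.action_taken), j] += lr * (e.reward - q) * e.x[j]
    return model.weights + agg / len(batch)


class TestQBatchUpdate:
    def test_identical_batch_equals_single_delta(self, unit_scaler):
        rng = np.random.default_rng(0)
        model = QPolicyModel(rng.normal(size=(4, 9)), unit_scaler)
        e = _exp(rng.normal(size=9), Action.AAM, -1.5)
        updated = q_batch_update(model, [e] * 8, RLTrainConfig())
        expected = model.weights + q_single_delta(model, e, 0.01)
        np.testing.assert_allclose(updated.weights, expected, rtol=1e-12)

    def test_matches_independent_oracle_exactly(self, unit_scaler):
        rng = np.random.default_rng(4)
        model = QPolicyModel(rng.normal(size=(4, 9)), unit_scaler)
        batch = [
            _exp(rng.normal(size=9), Action(int(rng.integers(4))), float(rng.normal()))
            for _ in range(8)
        ]
        updated = q_batch_update(model, batch, RLTrainConfig())
        np.testing.assert_array_equal(
            updated.weights, _oracle_batch_mean(model, batch, 0.01)
        )

    def test_permutation_invariance(self, unit_scaler):
        rng = np.random.default_rng(5)
        model = QPolicyModel(rng.normal(size=(4, 9)), unit_scaler)
        batch = [
            _exp(rng.normal(size=9), Action(int(rng.integers(4))), float(rng.normal()))
            for _ in range(8)
        ]
        a = q_batch_update(model, batch, RLTrainConfig())
        for _ in range(5):
            perm = [batch[i] for i in rng.permutation(8)]
            b = q_batch_update(model, perm, RLTrainConfig())
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_rewards_matching_q_leave_weights_unchanged(self, unit_scaler):
        rng = np.random.default_rng(6)
        model = QPolicyModel(rng.normal(size=(4, 9)), unit_scaler)
        batch = []
        for _ in range(8):
            x = rng.normal(size=9)
            a = Action(int(rng.integers(4)))
            batch.append(_exp(x, a, float(model.weights[int(a)] @ x)))
        updated = q_batch_update(model, batch, RLTrainConfig())
        np.testing.assert_allclose(updated.weights, model.weights, atol=1e-12)

    def test_empty_batch_rejected(self, zero_model):
        with pytest.raises(EmptyBatchError):
            q_batch_update(zero_model, [], RLTrainConfig())

    def test_counters_incremented(self, zero_model):
        updated = q_batch_update(zero_model, [_exp(_e1(), Action.RAC, -1.0)] * 8)
        assert updated.updates_applied == 1
        assert updated.experiences_seen == 8

    def test_sum_aggregation(self, unit_scaler):
        model = QPolicyModel.zeros(unit_scaler)
        e = _exp(_e1(), Action.RAC, -2.0)
        cfg = RLTrainConfig(batch_aggregation="sum")
        updated = q_batch_update(model, [e] * 8, cfg)
        assert updated.weights[0, 0] == pytest.approx(8 * 0.01 * -2.0)


class TestRLTrain:
    def test_sixteen_experiences_two_updates(self, zero_model):
        exps = [_exp(_e1(), Action.RAC, -1.0)] * 16
        model = rl_train(zero_model, exps, RLTrainConfig())
        assert model.updates_applied == 2
        assert model.experiences_seen == 16
        assert model.pending == ()

    def test_empty_stream_noop(self, zero_model):
        model = rl_train(zero_model, [], RLTrainConfig())
        assert model.updates_applied == 0
        np.testing.assert_array_equal(model.weights, zero_model.weights)

    def test_partial_batch_held_pending(self, zero_model):
        exps = [_exp(_e1(), Action.RAC, -1.0)] * 11
        model = rl_train(zero_model, exps, RLTrainConfig())
        assert model.updates_applied == 1
        assert len(model.pending) == 3

    def test_pending_resumes_on_next_call(self, zero_model):
        cfg = RLTrainConfig()
        first = rl_train(zero_model, [_exp(_e1(), Action.RAC, -1.0)] * 11, cfg)
        resumed = rl_train(first, [_exp(_e1(), Action.RAC, -1.0)] * 5, cfg)
        assert resumed.updates_applied == 2
        assert resumed.pending == ()
        # identical to one uninterrupted stream of 16
        direct = rl_train(zero_model, [_exp(_e1(), Action.RAC, -1.0)] * 16, cfg)
        np.testing.assert_array_equal(resumed.weights, direct.weights)

    def test_flush_partial_applies_remainder(self, zero_model):
        model = rl_train(
            zero_model, [_exp(_e1(), Action.RAC, -1.0)] * 11, RLTrainConfig(),
            flush_partial=True,
        )
        assert model.updates_applied == 2
        assert model.pending == ()

    def test_arrival_order_batching(self, unit_scaler):
        # first batch of 8 all RAC, second all EXC: RAC row must reflect the
        # first update only, computed at zero weights
        exps = [_exp(_e1(), Action.RAC, -2.0)] * 8 + [_exp(_e1(), Action.EXC, -1.0)] * 8
        model = rl_train(QPolicyModel.zeros(unit_scaler), exps, RLTrainConfig())
        assert model.weights[0, 0] == pytest.approx(0.01 * -2.0)
        assert model.weights[1, 0] == pytest.approx(0.01 * -1.0)


class TestGreedyAction:
    def test_all_tie_breaks_to_rac(self, zero_model):
        assert greedy_action(zero_model, _e1()) is Action.RAC

    def test_argmax(self, unit_scaler):
        V = np.zeros((4, 9))
        V[:, 0] = [-1.0, -0.2, -3.0, -0.5]
        model = QPolicyModel(V, unit_scaler)
        assert greedy_action(model, _e1()) is Action.EXC

    def test_tie_between_later_actions(self, unit_scaler):
        V = np.zeros((4, 9))
        V[:, 0] = [-1.0, 0.5, 0.5, -0.5]
        model = QPolicyModel(V, unit_scaler)
        assert greedy_action(model, _e1()) is Action.EXC

    def test_epsilon_zero_is_greedy(self, unit_scaler):
        V = np.zeros((4, 9))
        V[3, 0] = 1.0
        model = QPolicyModel(V, unit_scaler)
        rng = np.random.default_rng(0)
        assert all(
            epsilon_greedy_action(model, _e1(), 0.0, rng) is Action.AFA
            for _ in range(20)
        )

    def test_epsilon_one_explores_all(self, zero_model):
        rng = np.random.default_rng(0)
        seen = {epsilon_greedy_action(zero_model, _e1(), 1.0, rng) for _ in range(200)}
        assert seen == set(Action)


class TestWarmStart:
    def test_greedy_matches_sl_argmax(self, unit_scaler):
        rng = np.random.default_rng(12)
        W = rng.normal(size=(4, 9))
        sl = SLPolicyModel(W, unit_scaler)
        q = warm_start_from_sl(sl, scale=0.5)
        for _ in range(50):
            x = np.concatenate([[1.0], rng.normal(size=8)])
            assert int(greedy_action(q, x)) == int(np.argmax(W @ x))


@settings(max_examples=100, deadline=None)
@given(
    v=st.lists(st.floats(-5, 5), min_size=36, max_size=36),
    x=st.lists(st.floats(-2, 2), min_size=8, max_size=8),
    r=st.floats(-4, 0),
    a=st.integers(0, 3),
    lr=st.floats(0.001, 0.15),
)
def test_single_step_contraction_property(v, x, r, a, lr):
    """|r - Q(x,a)| never increases after one update when 0 < lr ||x||^2 < 2."""
    scaler = FeatureScaler((0, 0, 0, 0), (1, 1, 1, 1))
    vec = np.concatenate([[1.0], x])
    if not (0 < lr * float(vec @ vec) < 2):
        return
    model = QPolicyModel(np.array(v).reshape(4, 9), scaler)
    e = Experience(x=vec, action_taken=Action(a), reward=r)
    before = abs(r - q_predict(model, vec)[a])
    updated = QPolicyModel(model.weights + q_single_delta(model, e, lr), scaler)
    after = abs(r - q_predict(updated, vec)[a])
    assert after <= before + 1e-9
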