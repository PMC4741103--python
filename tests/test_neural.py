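"""Learning stack: VF prototypes, vigilance recruitment, LMS, STM, WTA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imitrec import (AssociativeMap, Config, STMBuffer, VFNetwork, learn_frame,
                     lms_step, one_hot, stm_update, vf_activities, vf_learn, wta)
from imitrec.neural import MotorInternalState, gated_activities
from imitrec.protocol import run_learning_phase


class TestVFActivities:
    def test_exact_match_gives_one(self, rng):
        v = rng.random(32)
        net = VFNetwork()
        vf_learn(v, net)
        assert vf_activities(v, net)[0] == 1.0

    def test_uniform_offset_hand_value(self):
        net = VFNetwork()
        proto = np.full(10, 0.5)
        vf_learn(proto, net)
        view = proto + 0.1
        assert np.isclose(vf_activities(view, net)[0], 0.9)

    def test_monotone_in_l1_distance(self, rng):
        net = VFNetwork()
        proto = rng.random(64)
        vf_learn(proto, net)
        acts = []
        for eps in np.linspace(0, 0.5, 11):
            acts.append(vf_activities(proto + eps, net)[0])
        diffs = np.diff(acts)
        assert np.all(diffs <= 1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        net = VFNetwork()
        for _ in range(3):
            vf_learn(r.random(16), net)
        a = vf_activities(r.random(16), net)
        assert np.all((a >= 0.0) & (a <= 1.0))

    def test_empty_network_empty_vector(self):
        assert vf_activities(np.zeros(4), VFNetwork()).size == 0


class TestVFLearn:
    def test_first_view_recruited_one_shot(self, rng):
        v = rng.random(20)
        net = VFNetwork()
        net, j, recruited = vf_learn(v, net, t=5)
        assert recruited and j == 0
        assert np.array_equal(net.prototypes[0], v)
        assert net.recruit_log == [(5, 0)]

    def test_representing_same_view_changes_nothing(self, rng):
        v = rng.random(20)
        net = VFNetwork()
        vf_learn(v, net)
        before = net.prototypes.copy()
        net, k, recruited = vf_learn(v, net)
        assert not recruited and k == 0
        assert np.array_equal(net.prototypes, before)

    def test_winner_update_rule_arithmetic(self):
        # prototype p, view at activity 0.9, epsilon 0.1:
        # new weights = p + 0.1 * (v - p) * (1 - 0.9)
        net = VFNetwork(gamma=0.5, epsilon=0.1)
        p = np.full(10, 0.4)
        vf_learn(p, net)
        v = p + 0.1  # VF = 0.9
        net, k, recruited = vf_learn(v, net)
        assert not recruited
        expected = p + 0.1 * (v - p) * (1 - 0.9)
        assert np.allclose(net.prototypes[0], expected)

    def test_below_vigilance_recruits(self):
        net = VFNetwork(gamma=0.95)
        vf_learn(np.zeros(10), net)
        net, j, recruited = vf_learn(np.full(10, 0.2), net)  # activity 0.8 < gamma
        assert recruited and j == 1

    def test_non_finite_view_rejected(self):
        with pytest.raises(ValueError):
            vf_learn(np.array([0.1, np.nan]), VFNetwork())

    def test_gating_silences_subvigilance(self):
        a = np.array([0.99, 0.5, 0.96])
        assert np.array_equal(gated_activities(a, 0.96), np.array([0.99, 0.0, 0.96]))


class TestLMS:
    def test_zero_error_leaves_weights(self, rng):
        amap = AssociativeMap(rng.random((3, 4)), learning_rate=0.5)
        x = rng.random(4)
        before = amap.weights.copy()
        lms_step(x, amap.predict(x), amap)
        assert np.allclose(amap.weights, before)

    def test_one_dimensional_step(self):
        amap = AssociativeMap(np.zeros((1, 1)), learning_rate=0.5)
        lms_step(np.array([1.0]), np.array([1.0]), amap)
        assert np.isclose(amap.weights[0, 0], 0.5)

    def test_converges_to_normal_equations(self, rng):
        """Repeated epochs reach the least-squares solution of a solvable
        toy problem, checked against the closed-form oracle."""
        X = rng.random((12, 4))
        W_true = rng.random((2, 4))
        Y = X @ W_true.T
        W_ls = np.linalg.lstsq(X, Y, rcond=None)[0].T  # normal-equations oracle
        amap = AssociativeMap(np.zeros((2, 4)), learning_rate=0.1)
        for _ in range(4000):
            for x, y in zip(X, Y):
                lms_step(x, y, amap)
        assert np.max(np.abs(amap.weights - W_ls)) < 1e-3

    def test_dimension_mismatch_rejected(self):
        amap = AssociativeMap(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            lms_step(np.zeros(4), np.zeros(2), amap)
        with pytest.raises(ValueError):
            lms_step(np.zeros(3), np.zeros(5), amap)

    def test_growth_pads_with_zeros(self):
        amap = AssociativeMap(np.ones((2, 2)))
        amap.grow_inputs(4)
        assert amap.weights.shape == (2, 4)
        assert np.all(amap.weights[:, 2:] == 0)
        amap.grow_outputs(3)
        assert amap.weights.shape == (3, 4)
        assert np.all(amap.weights[2] == 0)
        with pytest.raises(ValueError):
            amap.grow_inputs(1)


class TestSTM:
    def test_memoryless_identity_at_zero_decay(self, rng):
        buf = STMBuffer.zeros(3, decay=0.0)
        x = rng.random(3)
        assert np.allclose(stm_update(buf, x), x)

    def test_constant_input_fixed_point(self):
        buf = STMBuffer.zeros(2, decay=0.7)
        c = np.array([0.3, 0.8])
        for _ in range(200):
            out = stm_update(buf, c)
        assert np.allclose(out, c, atol=1e-10)

    def test_recurrence_arithmetic(self):
        buf = STMBuffer.zeros(1, decay=0.5)
        assert np.isclose(stm_update(buf, np.array([1.0]))[0], 0.5)
        assert np.isclose(stm_update(buf, np.array([0.0]))[0], 0.25)

    def test_reset_zeroes_state(self):
        buf = STMBuffer.zeros(2, decay=0.5)
        stm_update(buf, np.ones(2))
        buf.reset()
        assert np.all(buf.state == 0)


class TestWTA:
    @pytest.mark.parametrize("vec,winner", [([0.1, 0.9, 0.3], 1), ([0.4, 0.4], 0), ([2.0], 0)])
    def test_examples(self, vec, winner):
        assert wta(np.array(vec)) == winner

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_linear_scan(self, seed):
        v = np.random.default_rng(seed).random(17)
        best, arg = -np.inf, -1
        for i, x in enumerate(v):
            if x > best:
                best, arg = x, i
        assert wta(v) == arg

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wta(np.array([]))


def test_motor_internal_state_one_hot():
    mis = MotorInternalState(3)
    assert np.array_equal(mis.one_hot, np.array([0, 0, 0, 1, 0]))
    with pytest.raises(ValueError):
        MotorInternalState(5)
    with pytest.raises(ValueError):
        one_hot(-1, 5)


class TestLearnFrame:
    def test_recruit_count_bounded_by_views(self, rng):
        views = [rng.random(16) for _ in range(8)]
        net = VFNetwork()
        misp = AssociativeMap.empty(5, 0.1)
        log = learn_frame(views, one_hot(2, 5), net, misp)
        assert log["recruits"] <= len(views)
        assert log["neuron_count"] == net.n_neurons <= len(views)
        assert misp.n_inputs == net.n_neurons

    def test_representing_frame_recruits_nothing(self, rng):
        views = [rng.random(16) for _ in range(5)]
        net = VFNetwork(gamma=0.9)
        misp = AssociativeMap.empty(5, 0.1)
        learn_frame(views, one_hot(0, 5), net, misp, t=0)
        before = len(net.recruit_log)
        learn_frame(views, one_hot(0, 5), net, misp, t=1)
        assert len(net.recruit_log) == before

    def test_neuron_count_nondecreasing_over_session(self, small_learning, small_cfg):
        net, misp, person, events, tlog, trace, _ = run_learning_phase(
            small_learning.frames[:40], small_cfg, {})
        counts = tlog["neuron_count"].to_numpy()
        assert np.all(np.diff(counts) >= 0)


def test_recruitment_monotone_in_vigilance(small_learning):
    """A stricter vigilance never recruits fewer neurons on the same stream."""
    import dataclasses

    base = Config(n_avatars=3, frames_per_partner=100)
    counts = []
    cache = {}
    for gamma in (0.80, 0.90, 0.95):
        cfg = dataclasses.replace(base, gamma=gamma)
        net, *_ = run_learning_phase(small_learning.frames[:30], cfg, cache)
        counts.append(net.n_neurons)
    assert counts[0] <= counts[1] <= counts[2]
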