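import numpy as np
import pytest

import bootstraphear as bh
from bootstraphear.angles import wrap_deg
from bootstraphear.learning import (ExpansionSchedule, PeakRelativeWorld,
                                    PolicyConfig, TrainConfig,
                                    discounted_returns, expansion_feedback,
                                    peak_seek_feedback, policy_episode,
                                    surrogate_batch_grads, surrogate_episode,
                                    train_bootstrap)
from bootstraphear.student import init_student
from bootstraphear.synthetic import make_toy_world
from bootstraphear.teacher import MidlineTeacher


class ToyEnv:
    """1-D toy environment over a ToyWorld feature map (3-dim inputs)."""

    level = 70.0

    def __init__(self, world):
        self.world = world

    def sample_levels(self, n, rng):
        return np.full(n, self.level)

    def observe(self, az, el=0.0, level=None, rng=None):
        return self.world.features(az)

    def magnitudes(self, az, el=0.0, level=None, rng=None):
        feats = self.world.features(az)
        return feats, np.zeros_like(feats)


class PerfectTeacher:
    """Error-free left/right discriminator reading the toy ILD feature."""

    side = "right"

    def response(self, left, right, rng):
        spike = (np.asarray(left)[..., 0] > 0).astype(float)
        return bh.TeacherOutput(spike=spike, rate=spike.copy())


# ----------------------------------------------------------------------
# Algorithm 1
# ----------------------------------------------------------------------

def test_surrogate_equals_l1_gradient_exactly():
    """With an error-free Teacher the batch gradient is the L1 gradient."""
    world = make_toy_world("linear_ild")
    env = ToyEnv(world)
    teacher = PerfectTeacher()
    rng_master = np.random.default_rng(0)
    for _ in range(10):
        seed = int(rng_master.integers(2**31))
        net = init_student(np.random.default_rng(seed), 3, 1,
                           hidden=6, n_hidden_layers=2)
        rng = np.random.default_rng(seed + 1)
        gw, gb, info = surrogate_batch_grads(env, teacher, net, 16, rng,
                                             (-170.0, 170.0))
        # direct route: backprop the analytic L1 sign given the true labels
        obs = env.observe(info["y_true"])
        out, acts = net.forward(obs)
        sign = np.sign(out[:, 0] - info["y_true"])
        gw2, gb2 = net.backward(acts, sign[:, None])
        for a, b in zip(gw + gb, gw2 + gb2):
            np.testing.assert_array_equal(a, b)


def test_surrogate_episode_record():
    world = make_toy_world("linear_ild")
    env, teacher = ToyEnv(world), PerfectTeacher()
    net = init_student(np.random.default_rng(0), 3, 1, hidden=6,
                       n_hidden_layers=2)
    ep = surrogate_episode(env, teacher, net, np.random.default_rng(1))
    assert ep.feedback.shape == (1,)
    assert ep.feedback[0] in (-1.0, 1.0)
    assert ep.surrogate_sign[0] == -ep.feedback[0]


def test_biased_teacher_induces_matching_offset():
    """Training against a step teacher with boundary beta converges to
    yhat = ytrue - beta on a one-parameter toy student."""
    world = make_toy_world("biased_teacher", {"beta": 7.0})
    rng = np.random.default_rng(0)
    offset = 0.0  # constant predictor for a fixed source angle
    y_true = 40.0
    lr = 0.5
    for _ in range(3000):
        feedback = world.step_feedback(y_true, offset)
        offset += lr * feedback
    assert offset == pytest.approx(y_true - 7.0, abs=1.0)


def test_zero_learning_rate_freezes_weights(env, lso_table, pop_teacher):
    net = bh.init_acoustic_student(np.random.default_rng(0), 48)
    before = net.flat.copy()
    cfg = TrainConfig(steps=30, lr=0.0, eval_interval=1000, seed=0)
    net, curve = train_bootstrap(env, pop_teacher, net, cfg)
    np.testing.assert_array_equal(net.flat, before)
    assert curve[0][1] == curve[-1][1]


def test_same_seed_identical_curves(env, pop_teacher):
    def run():
        cfg = TrainConfig(steps=120, eval_interval=40, seed=9)
        net = bh.init_acoustic_student(np.random.default_rng(9), 48)
        return train_bootstrap(env, pop_teacher, net, cfg,
                               np.random.default_rng(9))[1]

    assert run() == run()


def test_lr_schedule_linear_tail():
    cfg = TrainConfig(steps=1000, lr=1e-3, decay_frac=0.5)
    assert cfg.lr_at(0) == 1e-3
    assert cfg.lr_at(499) == 1e-3
    assert cfg.lr_at(750) == pytest.approx(5e-4)
    assert cfg.lr_at(999) == pytest.approx(1e-3 / 500)


# ----------------------------------------------------------------------
# Algorithm 2
# ----------------------------------------------------------------------

def test_return_arithmetic():
    """G1 = 5 for rewards (-5, +100) with gamma = 0.1."""
    returns = discounted_returns([-5.0, 100.0], gamma=0.1)
    assert returns[0] == pytest.approx(5.0)
    assert returns[1] == pytest.approx(100.0)


def test_returns_general_recursion():
    r = [1.0, 2.0, 3.0]
    g = discounted_returns(r, 0.5)
    assert g[2] == 3.0 and g[1] == 2.0 + 0.5 * 3.0
    assert g[0] == 1.0 + 0.5 * g[1]


def test_policy_episode_trace(env, lso_table):
    teacher = MidlineTeacher.from_table(lso_table)
    net = bh.init_acoustic_student(np.random.default_rng(0), 48)
    cfg = PolicyConfig(seed=0)
    ep = policy_episode(env, teacher, net, cfg, np.random.default_rng(2),
                        y_true=20.0)
    assert 1 <= len(ep.rewards) <= cfg.max_steps
    assert len(ep.poses) == len(ep.predictions) + 1
    assert set(np.unique(ep.rewards)) <= {-5.0, 100.0}
    np.testing.assert_allclose(
        ep.returns, discounted_returns(ep.rewards, cfg.gamma))


def test_ablated_reward_gives_zero_gradient(env):
    class NoReward:
        def response(self, left, right, rng):
            z = np.zeros(np.asarray(left).shape[:-1])
            return bh.TeacherOutput(spike=z, rate=z)

    from bootstraphear.learning import _policy_batch_grads

    net = bh.init_acoustic_student(np.random.default_rng(0), 48)
    cfg = PolicyConfig(seed=0, batch_size=8)
    gw, gb, _ = _policy_batch_grads(env, NoReward(), net, cfg,
                                    np.random.default_rng(1))
    # all returns equal -> baseline removes them -> exactly zero gradient
    assert all(np.all(g == 0) for g in gw) and all(np.all(g == 0) for g in gb)


def test_policy_config_validation():
    with pytest.raises(ValueError):
        PolicyConfig(sigma=0.0)
    with pytest.raises(ValueError):
        PolicyConfig(gamma=1.5)
    with pytest.raises(ValueError):
        PolicyConfig(max_steps=0)


# ----------------------------------------------------------------------
# peak seeking
# ----------------------------------------------------------------------

def test_peak_seek_direction_examples():
    resp = {-5.0: 3.0, 0.0: 5.0, 5.0: 4.0}
    assert peak_seek_feedback(lambda p: resp[p], 0.0, 5.0) == 0
    resp = {-5.0: 3.0, 0.0: 4.0, 5.0: 5.0}
    assert peak_seek_feedback(lambda p: resp[p], 0.0, 5.0) == 1
    resp = {-5.0: 5.0, 0.0: 4.0, 5.0: 3.0}
    assert peak_seek_feedback(lambda p: resp[p], 0.0, 5.0) == -1


def test_peak_seek_probe_clipped_with_warning():
    with pytest.warns(UserWarning):
        peak_seek_feedback(lambda p: -abs(p), 28.0, 5.0, rotation_limit=30.0)


def test_iterated_peak_seek_converges_to_monaural_peak(env):
    """Following the louder side finds the right-ear peak of the head model."""
    az = np.arange(-180.0, 180.0, 1.0)
    gl, gr = env.model.band_gains(az, 0.0)
    response = gr.mean(axis=-1)
    peak = az[np.argmax(response)]

    def listen_at(angle):
        g = env.model.band_gains(np.asarray(angle), 0.0)[1]
        return g.mean(axis=-1)

    eps = 5.0
    for start in (peak - 30.0, peak + 25.0, peak - 12.0):
        pos = start
        for _ in range(40):
            d = peak_seek_feedback(lambda p: listen_at(p), pos, eps,
                                   rotation_limit=360.0)
            if d == 0:
                break
            pos += d * eps
        assert abs(pos - peak) <= eps


# ----------------------------------------------------------------------
# range expansion
# ----------------------------------------------------------------------

def test_expansion_schedule_ranges():
    s = ExpansionSchedule()
    assert s.stage_range(2)[0] == (-60.0, 60.0)
    az6, el6 = s.stage_range(6)
    assert az6 == (-180.0, 180.0)
    assert el6 == (-40.0, 90.0)
    with pytest.raises(ValueError):
        ExpansionSchedule(eps=40.0)


def test_expansion_feedback_algebra(env):
    class PerfectInner:
        input_offset = 0.0
        input_scale = 1.0

        def forward(self, obs):
            # decode the azimuth from the toy observation (first entry)
            return np.asarray(obs)[..., :1].reshape(1, 1), None

    class AngleObsEnv:
        def observe(self, az, el=0.0, level=None, rng=None):
            return np.array([float(az)] * 3)

    # |y1| <= ell falls through to the innate procedure
    assert expansion_feedback(PerfectInner(), AngleObsEnv(), 20.0, 30.0,
                              50.0, 70.0, np.random.default_rng(0)) is None
    # perfect inner localiser: rotate to the 30-deg limit, see 20, report 50
    target = expansion_feedback(PerfectInner(), AngleObsEnv(), 50.0, 30.0,
                                50.0, 70.0, np.random.default_rng(0))
    assert target == pytest.approx(50.0)

    class BiasedInner(PerfectInner):
        def forward(self, obs):
            return np.asarray(obs)[..., :1].reshape(1, 1) + 4.0, None

    target = expansion_feedback(BiasedInner(), AngleObsEnv(), 50.0, 30.0,
                                50.0, 70.0, np.random.default_rng(0))
    assert target == pytest.approx(54.0)  # inherits the inner bias


def test_peak_relative_world_roundtrip(env):
    world = PeakRelativeWorld(env, grid_step=5.0)
    az, el = world.to_absolute(0.0, 0.0)
    assert az == pytest.approx(world.peak[0])
    # the relative origin is the loudest direction for the right ear
    near = world.monaural(np.array([0.0, 40.0, -40.0]), 0.0, 70.0, None)
    assert near[0] == max(near)


def test_spherical_phase_learns_within_rotation_range(env):
    """A short innate peak-seeking phase shrinks errors inside +-30 deg."""
    from bootstraphear.learning import (_spherical_phase, spherical_mae)
    from bootstraphear.student import AdamState

    rng = np.random.default_rng(0)
    world = PeakRelativeWorld(env, grid_step=5.0)
    net = bh.init_acoustic_student(rng, env.input_dim, output_dim=2)
    schedule = ExpansionSchedule(batch_size=8)
    state = AdamState.for_net(net, alpha=schedule.lr)
    before = spherical_mae(world, net, (-30, 30), (-30, 30), step=10.0)
    _spherical_phase(world, net, state, schedule, 6000, (-30.0, 30.0),
                     (-30.0, 30.0), 30.0, rng)
    after = spherical_mae(world, net, (-30, 30), (-30, 30), step=10.0)
    assert after["mae_mean_axis"] < before["mae_mean_axis"] * 0.75
    assert after["mae_azimuth"] < before["mae_azimuth"]
    assert after["mae_elevation"] < before["mae_elevation"]
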