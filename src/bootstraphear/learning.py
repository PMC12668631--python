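"""Interactive bootstrapping procedures.

Four ways a coarse innate Teacher can train the Student localiser without
external labels:

1. **Surrogate gradient** — the agent predicts, rotates toward its
   prediction, listens again, and the left/right Teacher's binary verdict
   replaces the sign term of the L1 regression gradient:
   grad = sign(yhat - ytrue) * d yhat / d theta, with the sign supplied by
   the Teacher spike.  With an error-free Teacher this equals the exact L1
   gradient.
2. **Intrinsic-reward policy gradient** — REINFORCE with a Gaussian policy
   whose mean is the Student output; the midline-detector Teacher's spike
   is the only reward (+100 on spike, -5 per step, discount 0.1, at most 3
   roll-out steps, exploration sigma 3.6 deg).
3. **Peak seeking** — with only a monaural circuit, the agent points its
   ear toward the sound by comparing loudness at yhat-eps, yhat, yhat+eps
   and following the louder side.
4. **Range expansion** — with head rotation limited to +-30 deg, the
   learned localiser itself becomes the next Teacher: rotate to the limit,
   re-estimate with the frozen previous-stage localiser, and use
   (second prediction + limit) as the training target, growing the learned
   range by 30 deg per stage until the full sphere is covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .angles import wrap_deg
from .student import AdamState, StudentNet, adam_step, init_acoustic_student

__all__ = [
    "TrainConfig", "PolicyConfig", "ExpansionSchedule", "Episode",
    "surrogate_episode", "surrogate_batch_grads", "train_bootstrap",
    "policy_episode", "train_policy", "discounted_returns",
    "peak_seek_feedback", "expansion_feedback", "PeakRelativeWorld",
    "train_spherical", "grid_signed_errors",
]


# ----------------------------------------------------------------------
# Configs
# ----------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Schedule for surrogate-gradient bootstrap training.

    The learning rate stays at ``lr`` and decays linearly to zero over the
    final ``decay_frac`` of training (the reference schedule decays over
    the last 60k of 160k steps, i.e. 0.375).
    """

    steps: int = 160_000
    batch_size: int = 32
    lr: float = 1e-3
    decay_frac: float = 0.375
    train_range: tuple[float, float] = (-180.0, 180.0)
    eval_interval: int = 2000
    rotation_limit: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if not 0.0 <= self.decay_frac <= 1.0:
            raise ValueError("decay_frac must lie in [0, 1]")

    def lr_at(self, step: int) -> float:
        decay_steps = int(round(self.steps * self.decay_frac))
        start = self.steps - decay_steps
        if step < start or decay_steps == 0:
            return self.lr
        return self.lr * max(self.steps - step, 0) / decay_steps


@dataclass
class PolicyConfig:
    """REINFORCE hyperparameters for the midline-reward procedure."""

    episodes: int = 200_000
    batch_size: int = 32
    lr: float = 3e-4
    decay_frac: float = 0.15  # lr -> 0 over the final 30k of 200k episodes
    sigma: float = 3.6
    max_steps: int = 3
    gamma: float = 0.1
    reward_success: float = 100.0
    reward_step: float = -5.0
    out_of_range: float = 90.0
    train_range: tuple[float, float] = (-90.0, 90.0)
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("exploration sigma must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.max_steps < 1:
            raise ValueError("need at least one roll-out step")

    def lr_at(self, update: int, n_updates: int) -> float:
        decay = int(round(n_updates * self.decay_frac))
        start = n_updates - decay
        if update < start or decay == 0:
            return self.lr
        return self.lr * max(n_updates - update, 0) / decay


@dataclass
class Episode:
    """Record of one agent-environment interaction."""

    y_true: np.ndarray
    predictions: np.ndarray
    poses: np.ndarray
    feedback: np.ndarray
    rewards: np.ndarray | None = None
    returns: np.ndarray | None = None
    surrogate_sign: np.ndarray | None = None


def _teacher_feedback_sign(teacher) -> float:
    """+1 if a spike means "source on the right" (right-side circuits)."""
    return 1.0 if getattr(teacher, "side", "right") == "right" else -1.0


# ----------------------------------------------------------------------
# Algorithm 1: surrogate gradient
# ----------------------------------------------------------------------

BRANCH_WALL_DEG = 540.0


def _branch_wall(y_hat, sign):
    """Keep the learned azimuth branch within 1.5 turns of the origin.

    Angles live on the circle: a prediction beyond +-540 deg encodes the
    same rotation as its wrapped value but degrades the wrapped-residual
    feedback (and eventually float precision), which can turn a transient
    oscillation into unbounded drift.  Outside the wall the surrogate sign
    is replaced by an inward pull; converged students never reach it.
    """
    out = np.asarray(sign, dtype=float)
    outside = np.abs(y_hat) > BRANCH_WALL_DEG
    if np.any(outside):
        out = np.where(outside, np.sign(y_hat), out)
    return out


def surrogate_batch_grads(env, teacher, net: StudentNet, batch: int,
                          rng: np.random.Generator,
                          train_range=(-180.0, 180.0)):
    """One batch of interactive episodes and the assembled surrogate gradient.

    Returns ``(grads_w, grads_b, info)``; the gradient is the mean over the
    batch of sign * d yhat / d theta, the surrogate of the mean-L1-loss
    gradient.
    """
    lo, hi = train_range
    y_true = rng.uniform(lo, hi, batch)
    levels = env.sample_levels(batch, rng)
    obs = env.observe(y_true, 0.0, levels, rng)
    out, acts = net.forward(obs)
    y_hat = out[:, 0]
    residual = wrap_deg(y_true - y_hat)
    left, right = env.magnitudes(residual, 0.0, levels, rng)
    response = teacher.response(left, right, rng)
    feedback = _teacher_feedback_sign(teacher) * (2.0 * response.spike - 1.0)
    sign = -feedback  # approx sign(yhat - ytrue)
    sign = _branch_wall(y_hat, sign)
    grad_out = np.zeros_like(out)
    grad_out[:, 0] = sign
    grads_w, grads_b = net.backward(acts, grad_out, reuse_buffer=True)
    info = {"y_true": y_true, "y_hat": y_hat, "residual": residual,
            "feedback": feedback}
    return grads_w, grads_b, info


def surrogate_episode(env, teacher, net: StudentNet,
                      rng: np.random.Generator,
                      train_range=(-180.0, 180.0)) -> Episode:
    """A single interactive episode with its surrogate gradient sign."""
    grads_w, grads_b, info = surrogate_batch_grads(
        env, teacher, net, 1, rng, train_range)
    return Episode(
        y_true=info["y_true"], predictions=info["y_hat"],
        poses=info["y_hat"].copy(), feedback=info["feedback"],
        surrogate_sign=-info["feedback"],
    )


def grid_signed_errors(net: StudentNet, env, grid=None,
                       eval_seed: int = 12345, level: float | None = None
                       ) -> np.ndarray:
    """Signed wrapped errors (yhat - ytrue) on a fixed evaluation grid.

    Evaluation stimuli use a dedicated RNG seed independent of training,
    so repeated evaluations are deterministic.
    """
    if grid is None:
        grid = np.arange(-180.0, 180.0, 5.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(eval_seed)
    obs = env.observe(grid, 0.0, level, rng)
    y_hat = net.forward(obs)[0][:, 0]
    return wrap_deg(y_hat - grid)


def train_bootstrap(env, teacher, net: StudentNet, cfg: TrainConfig,
                    rng: np.random.Generator | None = None,
                    eval_grid=None):
    """Algorithm-1 training loop: batches of 32 episodes per Adam step.

    Returns ``(net, curve)`` where ``curve`` is a list of
    ``(step, mae_deg)`` pairs recorded every ``cfg.eval_interval`` steps.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    state = AdamState.for_net(net, alpha=cfg.lr)
    curve = []
    for step in range(cfg.steps):
        if step % cfg.eval_interval == 0:
            mae = float(np.abs(
                grid_signed_errors(net, env, eval_grid)).mean())
            curve.append((step, mae))
        gw, gb, _ = surrogate_batch_grads(
            env, teacher, net, cfg.batch_size, rng, cfg.train_range)
        adam_step(net, gw, gb, state, lr=cfg.lr_at(step))
    mae = float(np.abs(grid_signed_errors(net, env, eval_grid)).mean())
    curve.append((cfg.steps, mae))
    return net, curve


# ----------------------------------------------------------------------
# Algorithm 2: intrinsic-reward policy gradient
# ----------------------------------------------------------------------

def discounted_returns(rewards, gamma: float) -> np.ndarray:
    """G_t = sum_k gamma^(k-t) r_k for one episode's reward sequence."""
    rewards = np.asarray(rewards, dtype=float)
    returns = np.zeros_like(rewards)
    acc = 0.0
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        returns[t] = acc
    return returns


def policy_episode(env, midline_teacher, net: StudentNet, cfg: PolicyConfig,
                   rng: np.random.Generator, y_true: float | None = None
                   ) -> Episode:
    """Roll out one episode of Algorithm 2 and compute its returns.

    The state is the sound heard at the current head-relative source angle;
    the action is a rotation sampled from N(mu(s), sigma^2).  The episode
    ends on a Teacher spike (+100), after ``max_steps`` steps, or when the
    residual leaves the +-90 deg range; every non-success step costs -5.
    """
    lo, hi = cfg.train_range
    if y_true is None:
        y_true = float(rng.uniform(lo, hi))
    level = float(env.sample_levels(1, rng)[0])
    residual = y_true
    states, actions, rewards, poses = [], [], [], [0.0]
    for _ in range(cfg.max_steps):
        obs = env.observe(residual, 0.0, level, rng)
        mu = float(net.forward(obs)[0][0, 0])
        action = mu + cfg.sigma * rng.standard_normal()
        residual = float(wrap_deg(residual - action))
        poses.append(poses[-1] + action)
        left, right = env.magnitudes(residual, 0.0, level, rng)
        spike = float(midline_teacher.response(left, right, rng).spike)
        states.append(obs)
        actions.append(action)
        if spike:
            rewards.append(cfg.reward_success)
            break
        rewards.append(cfg.reward_step)
        if abs(residual) > cfg.out_of_range:
            break
    returns = discounted_returns(rewards, cfg.gamma)
    return Episode(
        y_true=np.array([y_true]), predictions=np.asarray(actions),
        poses=np.asarray(poses), feedback=np.asarray(rewards),
        rewards=np.asarray(rewards), returns=returns,
    )


def _policy_batch_grads(env, teacher, net, cfg: PolicyConfig,
                        rng: np.random.Generator):
    """Vectorized batch of episodes; REINFORCE gradient, averaged per episode."""
    batch = cfg.batch_size
    lo, hi = cfg.train_range
    residual = rng.uniform(lo, hi, batch)
    levels = env.sample_levels(batch, rng)
    alive = np.ones(batch, dtype=bool)
    step_obs, step_actions, step_mu, step_idx = [], [], [], []
    rewards = np.zeros((cfg.max_steps, batch))
    active = np.zeros((cfg.max_steps, batch), dtype=bool)
    for t in range(cfg.max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        obs = env.observe(residual[idx], 0.0, levels[idx], rng)
        mu = net.forward(obs)[0][:, 0]
        action = mu + cfg.sigma * rng.standard_normal(idx.size)
        residual[idx] = wrap_deg(residual[idx] - action)
        left, right = env.magnitudes(residual[idx], 0.0, levels[idx], rng)
        spike = teacher.response(left, right, rng).spike
        rewards[t, idx] = np.where(spike > 0, cfg.reward_success,
                                   cfg.reward_step)
        active[t, idx] = True
        step_obs.append(obs)
        step_actions.append(action)
        step_mu.append(mu)
        step_idx.append(idx)
        ended = (spike > 0) | (np.abs(residual[idx]) > cfg.out_of_range)
        alive[idx[ended]] = False
    # per-episode discounted returns
    returns = np.zeros_like(rewards)
    acc = np.zeros(batch)
    for t in range(cfg.max_steps - 1, -1, -1):
        acc = rewards[t] + cfg.gamma * acc * active[t]
        returns[t] = np.where(active[t], acc, 0.0)
    # assemble ascent gradient: sum_t grad log pi * (G_t - b_t), averaged
    # over the batch.  b_t is the batch-mean return at roll-out step t, a
    # standard state-independent baseline: it leaves the expected policy
    # gradient unchanged and removes the variance contributed by episodes
    # whose returns carry no action information (e.g. far sources that
    # collect only step penalties).
    all_obs = np.concatenate(step_obs, axis=0)
    rows_sign = []
    for t, (action, mu, idx) in enumerate(zip(step_actions, step_mu, step_idx)):
        g = returns[t, idx]
        g = g - g.mean()
        rows_sign.append((action - mu) / cfg.sigma**2 * g)
    coeff = np.concatenate(rows_sign)
    out, acts = net.forward(all_obs)
    grad_out = np.zeros_like(out)
    # descent on -J; backward averages over rows, rescale to mean per episode
    grad_out[:, 0] = -coeff * (all_obs.shape[0] / batch)
    gw, gb = net.backward(acts, grad_out, reuse_buffer=True)
    mean_return = float(returns[0].mean())
    return gw, gb, mean_return


def train_policy(env, midline_teacher, net: StudentNet, cfg: PolicyConfig,
                 rng: np.random.Generator | None = None,
                 eval_grid=None, eval_interval_updates: int = 200):
    """Algorithm-2 training loop over ``cfg.episodes`` episodes.

    Returns ``(net, curve)`` with ``curve`` a list of
    ``(episodes_seen, mae_deg, mean_return)`` tuples on the frontal grid.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if eval_grid is None:
        eval_grid = np.arange(-90.0, 91.0, 5.0)
    state = AdamState.for_net(net, alpha=cfg.lr)
    n_updates = max(cfg.episodes // cfg.batch_size, 1)
    curve = []
    for update in range(n_updates):
        gw, gb, mean_return = _policy_batch_grads(
            env, midline_teacher, net, cfg, rng)
        adam_step(net, gw, gb, state, lr=cfg.lr_at(update, n_updates))
        if update % eval_interval_updates == 0 or update == n_updates - 1:
            mae = float(np.abs(
                grid_signed_errors(net, env, eval_grid)).mean())
            curve.append((update * cfg.batch_size, mae, mean_return))
            if not np.isfinite(mean_return):
                raise FloatingPointError("divergent returns")
    return net, curve


# ----------------------------------------------------------------------
# Peak seeking and range expansion
# ----------------------------------------------------------------------

def peak_seek_feedback(listen, y_hat: float, eps: float,
                       rotation_limit: float = 30.0) -> int:
    """Compare loudness at y_hat-eps, y_hat, y_hat+eps; follow the louder side.

    ``listen(angle)`` returns the monaural response with the head rotated to
    ``angle``.  Returns +1 if the clockwise probe is loudest, -1 for the
    counter-clockwise probe, 0 if the centre is loudest (aligned).  Probes
    beyond the rotation limit are clipped (with a warning).
    """
    probes = np.array([y_hat - eps, y_hat, y_hat + eps])
    clipped = np.clip(probes, -rotation_limit, rotation_limit)
    if not np.array_equal(probes, clipped):
        warnings.warn("peak-seek probe clipped to the rotation limit",
                      stacklevel=2)
    responses = [float(listen(p)) for p in clipped]
    best = int(np.argmax(responses))
    return (-1, 0, 1)[best]


def expansion_feedback(net_as_teacher: StudentNet, env, y1: float,
                       ell: float, y_true: float, level: float,
                       rng: np.random.Generator) -> float | None:
    """Self-bootstrapped target for a first prediction beyond the limit.

    If ``|y1| <= ell`` the sample falls through to the innate procedure
    (returns None).  Otherwise the agent rotates to the signed limit,
    listens again, lets the frozen previous-stage localiser predict the
    remaining offset y2, and returns y2 + sign(y1)*ell as the corrected
    training target.
    """
    if abs(y1) <= ell:
        return None
    pose = float(np.sign(y1) * ell)
    obs = env.observe(wrap_deg(y_true - pose), 0.0, level, rng)
    y2 = float(net_as_teacher.forward(obs)[0][0, 0])
    return y2 + pose


@dataclass
class ExpansionSchedule:
    """Stage layout of the range-expansion curriculum.

    Stage i trains on azimuth +-min(30*i, 180) and elevation
    [max(-30*i, el_min), min(30*i, el_max)] (peak-relative coordinates),
    reaching full coverage at stage 6.  Stage 1 is learned from the innate
    monaural Teacher (two phases: peak seeking, then a refinement pass on
    (-40, 40) with rotation limited to +-20); stages 2..6 use the frozen
    previous-stage localiser as Teacher with weight duplication.
    """

    n_stages: int = 6
    step_deg: float = 30.0
    az_cap: float = 180.0
    el_range: tuple[float, float] = (-40.0, 90.0)
    rotation_limit: float = 30.0
    refine_range: float = 40.0
    refine_rotation: float = 20.0
    eps: float = 5.0
    weight_duplication: bool = True
    stage1_steps: int = 300_000
    refine_steps: int = 100_000
    expand_steps: int = 100_000
    batch_size: int = 4
    lr: float = 1e-3
    decay_frac: float = 0.4

    def stage_range(self, i: int):
        az = min(self.step_deg * i, self.az_cap)
        el_lo = max(-self.step_deg * i, self.el_range[0])
        el_hi = min(self.step_deg * i, self.el_range[1])
        return (-az, az), (el_lo, el_hi)

    def __post_init__(self):
        if self.eps >= self.rotation_limit:
            raise ValueError("peak-seek eps must be below the rotation limit")


class PeakRelativeWorld:
    """The spherical environment in coordinates relative to the ear peak.

    The monaural response map of the chosen ear has a unique peak; the
    spherical localiser is learned in offsets (u, v) from that peak (the
    agent's motor zero).  Absolute angles are recovered by adding the peak
    position back.
    """

    def __init__(self, env, side: str = "right", grid_step: float = 1.0):
        from .angles import ELEVATION_MAX, ELEVATION_MIN

        self.env = env
        self.side = side
        az = np.arange(-180.0, 180.0, grid_step)
        el = np.arange(ELEVATION_MIN, ELEVATION_MAX + 1e-9, grid_step)
        A, E = np.meshgrid(az, el, indexing="ij")
        resp = env.monaural(A, E, None, None, side)
        i, j = np.unravel_index(np.argmax(resp), resp.shape)
        self.peak = (float(az[i]), float(el[j]))

    def to_absolute(self, u, v):
        return (wrap_deg(self.peak[0] + np.asarray(u, float)),
                np.clip(self.peak[1] + np.asarray(v, float), -40.0, 90.0))

    def observe(self, u, v, level, rng):
        az, el = self.to_absolute(u, v)
        return self.env.observe(az, el, level, rng)

    def monaural(self, u, v, level, rng):
        az, el = self.to_absolute(u, v)
        return self.env.monaural(az, el, level, rng, self.side)


def _peak_seek_signs(world: PeakRelativeWorld, u, v, pose_az, pose_el,
                     eps, rot, levels, rng):
    """Vectorized per-axis peak-seek directions for a batch, as grad signs."""
    def resp(paz, pel):
        return world.monaural(u - paz, v - pel, levels, rng)

    r_minus = resp(np.clip(pose_az - eps, -rot, rot), pose_el)
    r_center = resp(pose_az, pose_el)
    r_plus = resp(np.clip(pose_az + eps, -rot, rot), pose_el)
    d_az = np.select([(r_plus >= r_center) & (r_plus >= r_minus),
                      (r_minus >= r_center) & (r_minus > r_plus)],
                     [1.0, -1.0], default=0.0)
    e_minus = resp(pose_az, np.clip(pose_el - eps, -rot, rot))
    e_center = r_center
    e_plus = resp(pose_az, np.clip(pose_el + eps, -rot, rot))
    d_el = np.select([(e_plus >= e_center) & (e_plus >= e_minus),
                      (e_minus >= e_center) & (e_minus > e_plus)],
                     [1.0, -1.0], default=0.0)
    return -d_az, -d_el  # surrogate gradient signs


def _spherical_phase(world, net, state, schedule, steps, az_range, el_range,
                     rot, rng, teacher_net=None, lr=None, decay_frac=0.4):
    """One training phase (innate peak-seeking or expansion) of the 3D task."""
    batch = schedule.batch_size
    base_lr = lr if lr is not None else schedule.lr
    discarded = 0
    for step in range(steps):
        frac = step / max(steps, 1)
        decay_start = 1.0 - decay_frac
        lr_t = base_lr if frac < decay_start else \
            base_lr * (1.0 - frac) / max(decay_frac, 1e-9)
        u = rng.uniform(az_range[0], az_range[1], batch)
        v = rng.uniform(el_range[0], el_range[1], batch)
        levels = world.env.sample_levels(batch, rng)
        obs = world.observe(u, v, levels, rng)
        out, acts = net.forward(obs)
        y1_az, y1_el = out[:, 0], out[:, 1]
        grad_out = np.zeros_like(out)
        inner = (np.abs(y1_az) <= rot) & (np.abs(y1_el) <= rot)
        if teacher_net is None:
            inner[:] = True
        if inner.any():
            paz = np.clip(y1_az[inner], -rot, rot)
            pel = np.clip(y1_el[inner], -rot, rot)
            s_az, s_el = _peak_seek_signs(
                world, u[inner], v[inner], paz, pel,
                schedule.eps, rot, levels[inner], rng)
            # A probe from a clipped pose only reports the source's side
            # relative to the pose, not to the prediction: feedback that
            # would push a prediction further beyond the rotation limit is
            # uninformative there and is dropped (prevents runaway growth
            # when the sampling range exceeds the rotation range).
            s_az[(y1_az[inner] > rot) & (s_az < 0)] = 0.0
            s_az[(y1_az[inner] < -rot) & (s_az > 0)] = 0.0
            s_el[(y1_el[inner] > rot) & (s_el < 0)] = 0.0
            s_el[(y1_el[inner] < -rot) & (s_el > 0)] = 0.0
            grad_out[inner, 0] = s_az
            grad_out[inner, 1] = s_el
        outer = ~inner
        if teacher_net is not None and outer.any():
            paz = np.clip(y1_az[outer], -rot, rot)
            pel = np.clip(y1_el[outer], -rot, rot)
            obs2 = world.observe(u[outer] - paz, v[outer] - pel,
                                 levels[outer], rng)
            y2 = teacher_net.forward(obs2)[0]
            target_az = wrap_deg(y2[:, 0] + paz)
            target_el = y2[:, 1] + pel
            ok = ((target_az >= az_range[0]) & (target_az <= az_range[1]) &
                  (target_el >= el_range[0]) & (target_el <= el_range[1]))
            discarded += int((~ok).sum())
            rows = np.flatnonzero(outer)[ok]
            grad_out[rows, 0] = np.sign(wrap_deg(y1_az[rows] - target_az[ok]))
            grad_out[rows, 1] = np.sign(y1_el[rows] - target_el[ok])
        gw, gb = net.backward(acts, grad_out, reuse_buffer=True)
        adam_step(net, gw, gb, state, lr=lr_t)
    return discarded


def spherical_mae(world: PeakRelativeWorld, net: StudentNet,
                  az_range=(-180.0, 180.0), el_range=(-40.0, 90.0),
                  step: float = 10.0, eval_seed: int = 54321):
    """Per-axis MAE (and great-circle MAE) of the spherical localiser."""
    u = np.arange(az_range[0], az_range[1] + 1e-9, step)
    v = np.arange(el_range[0], el_range[1] + 1e-9, step)
    U, V = np.meshgrid(u, v, indexing="ij")
    rng = np.random.default_rng(eval_seed)
    obs = world.observe(U.ravel(), V.ravel(), None, rng)
    pred = net.forward(obs)[0]
    err_az = wrap_deg(pred[:, 0] - U.ravel())
    err_el = pred[:, 1] - V.ravel()
    gc = np.degrees(np.arccos(np.clip(
        np.sin(np.radians(V.ravel())) * np.sin(np.radians(V.ravel() + err_el))
        + np.cos(np.radians(V.ravel())) * np.cos(np.radians(V.ravel() + err_el))
        * np.cos(np.radians(err_az)), -1.0, 1.0)))
    return {
        "mae_azimuth": float(np.abs(err_az).mean()),
        "mae_elevation": float(np.abs(err_el).mean()),
        "mae_mean_axis": float(0.5 * (np.abs(err_az).mean()
                                      + np.abs(err_el).mean())),
        "mae_great_circle": float(gc.mean()),
    }


def train_spherical(env, schedule: ExpansionSchedule,
                    rng: np.random.Generator | None = None,
                    side: str = "right", net: StudentNet | None = None):
    """Full 3D curriculum: peak-seeking, refinement, then range expansion.

    Returns ``(net, world, stage_log)`` where ``stage_log`` maps stage
    labels to evaluation summaries on the stage's own range.
    """
    rng = rng or np.random.default_rng(0)
    world = PeakRelativeWorld(env, side=side)
    if net is None:
        net = init_acoustic_student(rng, input_dim=env.input_dim, output_dim=2)
    state = AdamState.for_net(net, alpha=schedule.lr)
    rot = schedule.rotation_limit
    stage_log = {}

    (az1, el1) = schedule.stage_range(1)
    _spherical_phase(world, net, state, schedule, schedule.stage1_steps,
                     az1, el1, rot, rng)
    _spherical_phase(world, net, state, schedule, schedule.refine_steps,
                     (-schedule.refine_range, schedule.refine_range),
                     (max(-schedule.refine_range, el1[0]),
                      min(schedule.refine_range, el1[1])),
                     schedule.refine_rotation, rng)
    stage_log["M1"] = spherical_mae(world, net, az1, el1)

    for i in range(2, schedule.n_stages + 1):
        az_i, el_i = schedule.stage_range(i)
        teacher_net = net.copy() if schedule.weight_duplication else net
        state = AdamState.for_net(net, alpha=schedule.lr)
        discarded = _spherical_phase(
            world, net, state, schedule, schedule.expand_steps,
            az_i, el_i, rot, rng, teacher_net=teacher_net)
        stage_log[f"M{i}"] = spherical_mae(world, net, az_i, el_i)
        stage_log[f"M{i}"]["discarded_targets"] = discarded
    return net, world, stage_log


def train_bootstrap_ensemble(env, teacher, seeds, cfg: TrainConfig,
                             rng: np.random.Generator | None = None):
    """Train several independently seeded Students at once (Algorithm 1).

    Each ensemble member runs the standard interactive procedure — its own
    initialisation, its own episodes (batch ``cfg.batch_size``), its own
    Adam moments — with the simulations stacked into batched array
    operations for throughput.  Returns the list of trained
    :class:`~bootstraphear.student.StudentNet` members.
    """
    from .student import StudentEnsemble, adam_step_ensemble

    rng = rng or np.random.default_rng(cfg.seed)
    ens = StudentEnsemble.acoustic(seeds, input_dim=env.input_dim)
    k, batch = ens.k, cfg.batch_size
    state = AdamState(m=np.zeros_like(ens.flat), v=np.zeros_like(ens.flat),
                      alpha=cfg.lr)
    lo, hi = cfg.train_range
    for step in range(cfg.steps):
        y_true = rng.uniform(lo, hi, (k, batch))
        levels = env.sample_levels(k * batch, rng).reshape(k, batch)
        obs = env.observe(y_true, 0.0, levels, rng)
        out, acts = ens.forward(obs)
        y_hat = out[..., 0]
        residual = wrap_deg(y_true - y_hat)
        left, right = env.magnitudes(residual, 0.0, levels, rng)
        response = teacher.response(left, right, rng)
        feedback = _teacher_feedback_sign(teacher) * (2.0 * response.spike
                                                      - 1.0)
        grad_out = np.zeros_like(out)
        grad_out[..., 0] = _branch_wall(y_hat, -feedback)
        grad = ens.backward(acts, grad_out)
        adam_step_ensemble(ens, grad, state, lr=cfg.lr_at(step))
    return [ens.member(i) for i in range(k)]
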