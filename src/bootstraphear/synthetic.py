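"""Seeded generators for every input the package needs without downloads.

* :func:`make_lso_table` — a synthetic stand-in for the 32-neuron LSO
  parameter set: sigmoid tuning with per-neuron jitter of half-activation
  ILD and slope, power-law rate variability, characteristic frequencies
  log-spaced over 20-2200 Hz.  This emulates the published dataset's
  structure, not its actual values (those are not printed anywhere).
* :func:`make_toy_world` — tiny 1-D worlds with closed-form optima, used
  as oracle substrates: a linear-ILD environment, an exactly biased step
  teacher, and a continuous-armed bandit with a known reward peak.
* :func:`child_seed` — the package-wide RNG policy: every component derives
  its own stream from (master seed, component name) by hashing, so
  experiments are reproducible per component and seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .teacher import PARAM_COLUMNS


def child_seed(master_seed: int, name: str) -> int:
    """Deterministic child seed derived from a master seed and a label."""
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def make_lso_table(n: int = 32, seed: int = 0) -> pd.DataFrame:
    """Generate ``n`` LSO parameter rows (a, b, c, d, g, h, cf).

    Distributional targets: half-activation ILD c ~ Normal(0, 3 dB), slope
    d ~ Uniform(1, 5 dB), offset/range (a, b) at plausible spike rates, and
    power-law variability (g, h) scaled so that sigma at a 20 dB ILD never
    exceeds 30% of the rate range b.  Deterministic under ``seed``.

    Half-activation points are drawn as signed magnitudes with alternating
    signs, and (|c|, d) values are shared within each +- pair of adjacent
    characteristic frequencies (both marginals are unchanged: c is still
    Normal(0, 3), d still Uniform(1, 5)).  Brainstem ILD circuits are
    bilaterally mirrored, so an ensemble's thresholds straddle the midline
    rather than drifting to one side; the pairing keeps the ensemble's
    decision boundary close to 0 degrees while individual neurons remain
    biased discriminators.
    """
    if n < 1:
        raise ValueError("need at least one neuron")
    rng = np.random.default_rng(seed)
    cf = np.geomspace(20.0, 2200.0, n)
    a = rng.uniform(5.0, 15.0, n)
    b = rng.uniform(60.0, 100.0, n)
    n_pairs = (n + 1) // 2
    c_mag = np.abs(rng.normal(0.0, 3.0, n_pairs))
    d_pair = rng.uniform(1.0, 5.0, n_pairs)
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    c = signs * np.repeat(c_mag, 2)[:n]
    d = np.repeat(d_pair, 2)[:n]
    h = rng.uniform(0.3, 0.7, n)
    sigma_frac = rng.uniform(0.05, 0.3, n)  # sigma/b at |x| = 20 dB
    g = sigma_frac * b / 20.0**h
    table = pd.DataFrame({"a": a, "b": b, "c": c, "d": d,
                          "g": g, "h": h, "cf": cf})
    return table[list(PARAM_COLUMNS)]


@dataclass
class ToyWorld:
    """A 1-D world on [-180, 180] with a known closed-form optimum.

    ``linear_ild``    : exact ILD x = k*sin(theta)*scale, a noiseless
                        feature map for small-network gradient tests; the
                        optimal localiser is the identity map.
    ``biased_teacher``: an error-free step discriminator whose decision
                        boundary sits exactly at ``beta`` degrees; a student
                        trained on it converges to yhat = ytrue - beta.
    ``bandit``        : a single-state continuous-armed bandit with a
                        Gaussian reward bump peaking at ``a_star``.
    """

    kind: str
    k: float = 0.5
    scale: float = 1.0
    beta: float = 0.0
    a_star: float = 30.0
    reward_width: float = 15.0
    seed: int = 0
    rng: np.random.Generator = field(init=False, repr=False)

    KINDS = ("linear_ild", "biased_teacher", "bandit")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown toy world kind {self.kind!r}")
        self.rng = np.random.default_rng(self.seed)

    # -- linear_ild ------------------------------------------------------
    def ild(self, theta):
        return self.k * np.sin(np.radians(np.asarray(theta, dtype=float))) \
            * self.scale

    def features(self, theta):
        """Deterministic low-dimensional input for a toy student, (..., 3)."""
        t = np.radians(np.asarray(theta, dtype=float))
        return np.stack([self.ild(theta), np.cos(t), np.sin(2 * t)], axis=-1)

    # -- biased_teacher --------------------------------------------------
    def step_feedback(self, y_true, y_hat):
        """Error-free discriminator: +1 iff the residual exceeds ``beta``.

        The residual is the wrapped difference y_true - y_hat; the boundary
        sits at exactly ``beta`` degrees, so the induced student equilibrium
        is yhat = ytrue - beta.
        """
        residual = wrap_deg(np.asarray(y_true, float) - np.asarray(y_hat, float))
        return np.where(residual > self.beta, 1.0, -1.0)

    # -- bandit ----------------------------------------------------------
    def bandit_reward(self, action):
        """Deterministic reward bump, max 100 at ``a_star``."""
        a = np.asarray(action, dtype=float)
        return 100.0 * np.exp(-0.5 * ((a - self.a_star) / self.reward_width) ** 2)


def make_toy_world(kind: str, params: dict | None = None, seed: int = 0) -> ToyWorld:
    """Construct a :class:`ToyWorld` of the given kind."""
    return ToyWorld(kind=kind, seed=seed, **(params or {}))
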