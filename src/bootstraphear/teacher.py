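"""Innate Teacher circuits.

The Teacher circuits are small hardwired models that supply coarse,
stochastic feedback for bootstrapping:

* :class:`SingleLSOTeacher` — one lateral-superior-olive neuron.  Its mean
  firing rate follows a sigmoid of ILD,

      mu(x) = a + b / (1 + exp((c - x) / d)),

  with trial-to-trial variability sigma(x) = g * |x|**h (the power law is
  symmetric in ILD magnitude; |x| makes it defined for negative ILDs and
  fractional exponents).  A normalized rate r is sampled from
  N(mu, sigma^2), mapped through Norm(r) = (r - a)/b (the theoretical
  floor/ceiling of the sigmoid) and clipped to [0, 1]; a binary spike is
  a Bernoulli draw with probability r.
* :class:`PopulationTeacher` — 32 LSO neurons with characteristic
  frequencies between 20 and 2200 Hz; their normalized rates are averaged
  and passed through a plastic sigmoid readout
  rho = logistic(w*rbar + b), initialized at (w, b) = (10, -5) which
  approximates the identity on [0, 1].
* :class:`MidlineTeacher` — left and right population circuits combined
  multiplicatively, r_M = Norm(rho_L * rho_R); it fires preferentially
  when the head faces the source and serves as an intrinsic reward.
* :class:`MonauralTeacher` — across-band mean magnitude of one ear, the
  substrate of the peak-seeking procedure.

A spike from a left/right discriminator teacher means "the source is on my
excitatory side"; the bootstrap procedures map a right-side spike to
feedback +1 (rotate clockwise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .acoustics import compute_ild

PARAM_COLUMNS = ("a", "b", "c", "d", "g", "h", "cf")


@dataclass
class LSOParams:
    """Sigmoid tuning parameters of one LSO neuron (rates in spikes/s)."""

    a: float  # rate offset
    b: float  # rate range
    c: float  # half-activation ILD (dB)
    d: float  # sigmoid slope (dB)
    g: float  # variability coefficient
    h: float  # variability exponent
    cf: float  # characteristic frequency (Hz)

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("rate range b must be positive")
        if self.d == 0:
            raise ValueError("slope d must be non-zero")


def load_lso_table(path) -> pd.DataFrame:
    """Load a user-supplied LSO parameter table (CSV with a,b,c,d,g,h,cf)."""
    table = pd.read_csv(path)
    missing = set(PARAM_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return table[list(PARAM_COLUMNS)].astype(float)


def lso_mean_rate(x, p: LSOParams):
    """Mean firing rate (spikes/s) of a neuron at ILD ``x`` dB."""
    x = np.asarray(x, dtype=float)
    return p.a + p.b / (1.0 + np.exp((p.c - x) / p.d))


def lso_std(x, p: LSOParams):
    """Rate standard deviation sigma = g*|x|^h at ILD ``x`` dB."""
    x = np.asarray(x, dtype=float)
    return p.g * np.abs(x) ** p.h


def sample_lso_rate(x, p: LSOParams, rng: np.random.Generator | None):
    """Normalized stochastic rate r in [0, 1]; ``rng=None`` gives the mean rate."""
    mu = lso_mean_rate(x, p)
    if rng is not None:
        mu = mu + rng.standard_normal(np.shape(mu)) * lso_std(x, p)
    return np.clip((mu - p.a) / p.b, 0.0, 1.0)


@dataclass
class TeacherOutput:
    """One stochastic read of a teacher: spike(s) in {0,1} and rate(s) in [0,1]."""

    spike: np.ndarray
    rate: np.ndarray


def sample_lso_spike(x, p: LSOParams, rng: np.random.Generator) -> TeacherOutput:
    """Bernoulli spike of a single neuron at ILD ``x``."""
    r = sample_lso_rate(x, p, rng)
    spike = (rng.random(np.shape(r)) < r).astype(float)
    return TeacherOutput(spike=spike, rate=r)


@dataclass
class ReadoutParams:
    """Plastic sigmoid readout of the population circuit."""

    w: float = 10.0
    b: float = -5.0

    def probability(self, rbar):
        return 1.0 / (1.0 + np.exp(-(self.w * np.asarray(rbar) + self.b)))

    @property
    def saturation(self) -> float:
        """rho at rbar = 1 (used to normalize the midline product)."""
        return float(self.probability(1.0))


class _ArrayParams:
    """Column-vector view of a parameter table for vectorized evaluation.

    Normalization bounds default to the theoretical floor/ceiling of the
    sigmoid, (a, a + b); :meth:`adapt_bounds` re-estimates them from the
    mean rates actually reached over an operating range (dynamic-range
    adaptation, used after cue disruptions).
    """

    def __init__(self, table: pd.DataFrame):
        for col in PARAM_COLUMNS:
            setattr(self, col, table[col].to_numpy(dtype=float))
        if np.any(self.b <= 0) or np.any(self.d == 0):
            raise ValueError("invalid LSO parameters (need b > 0, d != 0)")
        self.r_min = self.a.copy()
        self.r_range = self.b.copy()

    def mean_rates(self, x):
        return self.a + self.b / (1.0 + np.exp((self.c - x) / self.d))

    def adapt_bounds(self, x_grid):
        """Set Norm bounds to the empirical mean-rate range over ``x_grid``.

        ``x_grid`` has shape (n_points, n_members).  A small floor keeps the
        range positive when a member is fully saturated over the grid.
        """
        mu = self.mean_rates(x_grid)
        self.r_min = mu.min(axis=0)
        self.r_range = np.maximum(mu.max(axis=0) - self.r_min, 1e-6)

    def reset_bounds(self):
        self.r_min = self.a.copy()
        self.r_range = self.b.copy()

    def normalized_rates(self, x, rng):
        """Per-member normalized rates for ILDs ``x`` of shape (..., n)."""
        mu = self.mean_rates(x)
        if rng is not None:
            sigma = self.g * np.abs(x) ** self.h
            mu = mu + rng.standard_normal(np.shape(x)) * sigma
        return np.clip((mu - self.r_min) / self.r_range, 0.0, 1.0)


class SingleLSOTeacher:
    """Left/right discriminator built from one LSO neuron.

    The default characteristic frequency is 2000 Hz; the neuron with the
    nearest cf is taken from the supplied parameter table.
    """

    def __init__(self, table: pd.DataFrame, cf: float = 2000.0,
                 side: str = "right"):
        row = table.loc[(table["cf"] - cf).abs().idxmin()]
        self.params = LSOParams(**{k: float(row[k]) for k in PARAM_COLUMNS})
        self.side = side

    def ild(self, left_mags, right_mags):
        return compute_ild(left_mags, right_mags, self.params.cf, self.side)

    def response(self, left_mags, right_mags, rng) -> TeacherOutput:
        x = self.ild(left_mags, right_mags)
        r = sample_lso_rate(x, self.params, rng)
        spike = (rng.random(np.shape(r)) < r).astype(float)
        return TeacherOutput(spike=spike, rate=r)

    def mean_rate(self, left_mags, right_mags):
        """Deterministic normalized rate (noise-free), for characterisation."""
        x = self.ild(left_mags, right_mags)
        return sample_lso_rate(x, self.params, None)


class PopulationTeacher:
    """32-neuron LSO ensemble with a plastic sigmoid readout."""

    def __init__(self, table: pd.DataFrame, side: str = "right",
                 readout: ReadoutParams | None = None,
                 noise_scale: float = 1.0):
        if len(table) == 0:
            raise ValueError("population teacher needs at least one member")
        self.table = table.reset_index(drop=True)
        self.members = _ArrayParams(self.table)
        self.side = side
        self.readout = readout or ReadoutParams()
        self.noise_scale = float(noise_scale)
        # precompute the frequency-interpolation stencil at the member cfs
        from . import filterbank as fb

        fc = fb.center_frequencies()
        x_axis = fb.erb_rate(fc)
        e_cf = fb.erb_rate(self.members.cf)
        if np.any(self.members.cf < fc[0]) or np.any(self.members.cf > fc[-1]):
            raise ValueError("member characteristic frequency out of range")
        idx = np.clip(np.searchsorted(x_axis, e_cf) - 1, 0, len(x_axis) - 2)
        self._interp_idx = idx
        self._interp_w = (e_cf - x_axis[idx]) / (x_axis[idx + 1] - x_axis[idx])

    def member_ilds(self, left_mags, right_mags) -> np.ndarray:
        """ILD at each member's characteristic frequency, shape (..., n)."""
        diff = np.asarray(left_mags) - np.asarray(right_mags)
        if self.side == "right":
            diff = -diff
        idx, w = self._interp_idx, self._interp_w
        return diff[..., idx] * (1.0 - w) + diff[..., idx + 1] * w

    def _rbar(self, left_mags, right_mags, rng):
        x = self.member_ilds(left_mags, right_mags)
        if rng is not None and self.noise_scale != 1.0:
            m = self.members
            mu = m.mean_rates(x)
            sigma = self.noise_scale * m.g * np.abs(x) ** m.h
            mu = mu + rng.standard_normal(np.shape(x)) * sigma
            rates = np.clip((mu - m.r_min) / m.r_range, 0.0, 1.0)
        else:
            rates = self.members.normalized_rates(x, rng)
        return rates.mean(axis=-1)

    def adapt_normalization(self, env, grid=None, level: float | None = None
                            ) -> "PopulationTeacher":
        """Adapt member Norm bounds to the current operating range.

        Unsupervised dynamic-range adaptation: each member's normalization
        bounds are set to the minimum/maximum mean firing rate it actually
        reaches over an azimuth grid under the current (possibly disrupted)
        peripheral input.  No labels are involved and the fitted tuning
        parameters stay frozen; this models the firing-rate adaptation that
        keeps a circuit's output informative after its inputs shift, and is
        what makes two-label readout recalibration possible after an
        asymmetric disruption.
        """
        if grid is None:
            grid = np.arange(-90.0, 91.0, 1.0)
        left, right = env.magnitudes(np.asarray(grid, dtype=float), 0.0,
                                     level, None)
        x = self.member_ilds(left, right)
        self.members.adapt_bounds(x)
        return self

    def reset_normalization(self) -> "PopulationTeacher":
        self.members.reset_bounds()
        return self

    def probability(self, left_mags, right_mags, rng=None):
        """rho = logistic(w*rbar + b); stochastic if ``rng`` is given."""
        return self.readout.probability(self._rbar(left_mags, right_mags, rng))

    def response(self, left_mags, right_mags, rng) -> TeacherOutput:
        rho = self.probability(left_mags, right_mags, rng)
        spike = (rng.random(np.shape(rho)) < rho).astype(float)
        return TeacherOutput(spike=spike, rate=np.asarray(rho))

    def mean_rate(self, left_mags, right_mags):
        return self.probability(left_mags, right_mags, None)

    def mirrored(self) -> "PopulationTeacher":
        """The contralateral twin: same members, opposite excitatory ear."""
        other = "left" if self.side == "right" else "right"
        return PopulationTeacher(self.table, side=other,
                                 readout=replace(self.readout),
                                 noise_scale=self.noise_scale)


def population_teacher(left_mags, right_mags, table: pd.DataFrame,
                       readout: ReadoutParams, rng,
                       side: str = "right") -> TeacherOutput:
    """Functional form of the population circuit (one stochastic read)."""
    return PopulationTeacher(table, side, readout).response(
        left_mags, right_mags, rng)


class MidlineTeacher:
    """Multiplicative combination of left and right population circuits.

    r_M = Norm(rho_L * rho_R), normalized by the product's achievable peak.
    The two populations are mirrored, so their readouts cannot saturate
    simultaneously: the product is maximal with balanced input (rbar = 1/2
    on both sides, the midline), giving the circuit-intrinsic Norm bounds
    [0, rho_L(1/2) * rho_R(1/2)] with no empirical calibration.  The
    response therefore peaks at 1 when the head faces the source and the
    detector fires reliably at alignment.
    """

    def __init__(self, left: PopulationTeacher, right: PopulationTeacher):
        if left.side != "left" or right.side != "right":
            raise ValueError("expected a left-side and a right-side population")
        self.left = left
        self.right = right

    @classmethod
    def from_table(cls, table: pd.DataFrame, noise_scale: float = 1.0
                   ) -> "MidlineTeacher":
        right = PopulationTeacher(table, side="right", noise_scale=noise_scale)
        return cls(right.mirrored(), right)

    def _norm(self):
        peak = (float(self.left.readout.probability(0.5))
                * float(self.right.readout.probability(0.5)))
        return max(peak, 1e-12)

    def probability(self, left_mags, right_mags, rng=None):
        rho_l = self.left.probability(left_mags, right_mags, rng)
        rho_r = self.right.probability(left_mags, right_mags, rng)
        return np.clip(rho_l * rho_r / self._norm(), 0.0, 1.0)

    def response(self, left_mags, right_mags, rng) -> TeacherOutput:
        r_m = self.probability(left_mags, right_mags, rng)
        spike = (rng.random(np.shape(r_m)) < r_m).astype(float)
        return TeacherOutput(spike=spike, rate=np.asarray(r_m))

    def mean_rate(self, left_mags, right_mags):
        return self.probability(left_mags, right_mags, None)


def midline_detector(left_mags, right_mags, left_pop: PopulationTeacher,
                     right_pop: PopulationTeacher, rng) -> TeacherOutput:
    """Functional form of the midline-detector circuit (one read)."""
    return MidlineTeacher(left_pop, right_pop).response(
        left_mags, right_mags, rng)


class MonauralTeacher:
    """Across-band mean magnitude of one ear (overall monaural activity)."""

    def __init__(self, side: str = "right"):
        self.side = side

    def response_level(self, left_mags, right_mags):
        mags = left_mags if self.side == "left" else right_mags
        return np.asarray(mags).mean(axis=-1)


def monaural_response(left_mags, right_mags, side: str = "right"):
    """Mean of the 24 per-band magnitudes of the chosen ear."""
    return MonauralTeacher(side).response_level(left_mags, right_mags)


# ----------------------------------------------------------------------
# Characterisation
# ----------------------------------------------------------------------

@dataclass
class TeacherStats:
    """Empirical characterisation of a binary teacher over an azimuth grid."""

    grid: np.ndarray          # azimuths (deg)
    mean: np.ndarray          # per-angle mean spike rate
    variance: np.ndarray      # per-angle spike variance (ddof=0, <= 0.25)
    bias: float               # azimuth of the 0.5 crossing (deg); nan if none
    bias_defined: bool

    @property
    def variance_argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.variance))])


def _crossing_from_curve(grid: np.ndarray, mean: np.ndarray) -> tuple[float, bool]:
    """0.5 crossing of a noisy monotone response curve.

    The empirical mean curve is first smoothed with isotonic regression
    (monotone least squares, deterministic), in the direction implied by the
    curve's ends, then the crossing is linearly interpolated.
    """
    from sklearn.isotonic import IsotonicRegression

    k = max(len(grid) // 10, 1)
    increasing = mean[-k:].mean() >= mean[:k].mean()
    iso = IsotonicRegression(increasing=increasing, y_min=0.0, y_max=1.0)
    smooth = iso.fit_transform(grid, mean)
    s = smooth - 0.5 if increasing else 0.5 - smooth
    below = np.flatnonzero(s < 0.0)
    above = np.flatnonzero(s > 0.0)
    if below.size == 0 or above.size == 0:
        return float("nan"), False
    # isotonic curve: every s<0 index precedes every s>0 index
    i0 = int(below[-1])
    i1 = int(above[0])
    # a plateau at exactly 0.5 between i0 and i1 contributes its midpoint
    t = -s[i0] / (s[i1] - s[i0])
    return float(grid[i0] + t * (grid[i1] - grid[i0])), True


def estimate_teacher_stats(teacher, env, grid=None, n_samples: int = 100,
                           rng: np.random.Generator | None = None,
                           level: float | None = None) -> TeacherStats:
    """Sample a teacher across an azimuth grid and locate its bias.

    For each grid angle, ``n_samples`` independent presentations are made
    (fresh noise tokens) and the binary responses averaged.  The bias is the
    0.5 crossing of the (monotone-smoothed) mean spike-rate curve; the
    variance bound 0.25 of a Bernoulli variable holds per angle by
    construction (population variance, ddof=0).
    """
    if grid is None:
        grid = np.arange(-90.0, 91.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    rng = rng or np.random.default_rng()
    az = np.repeat(grid[None, :], n_samples, axis=0)
    left, right = env.magnitudes(az, 0.0, level, rng)
    out = teacher.response(left, right, rng)
    mean = out.spike.mean(axis=0)
    variance = out.spike.var(axis=0)  # ddof=0 -> bounded by 0.25
    bias, defined = _crossing_from_curve(grid, mean)
    return TeacherStats(grid=grid, mean=mean, variance=variance,
                        bias=bias, bias_defined=defined)


# ----------------------------------------------------------------------
# Readout plasticity
# ----------------------------------------------------------------------

def recalibrate_readout(teacher: PopulationTeacher, labeled_pairs,
                        steps: int = 1000, lr: float = 0.3,
                        env=None, rng: np.random.Generator | None = None
                        ) -> ReadoutParams:
    """Recalibrate (w, b) on binary left/right labels via gradient descent.

    Member LSO parameters are frozen; only the readout is plastic.  The
    descent minimizes the binary cross-entropy of rho against the labels
    (label 1 = "source on the teacher's excitatory side").

    Two stimulus conventions are supported:

    * ``env is None`` — ``labeled_pairs`` is ``((left_mags, right_mags),
      label)``: full-batch descent on fixed magnitude vectors, using the
      deterministic (mean-rate) population response.
    * ``env`` given — ``labeled_pairs`` is ``(angle_deg, label)``: the two
      sound sources persist while the readout adapts, so every descent
      step listens again (a fresh noise token and fresh member rates);
      this is stochastic gradient descent over the stimulus noise and
      converges to the boundary between the expected responses.

    The teacher's readout is updated in place and returned.
    """
    if len(labeled_pairs) == 0:
        raise ValueError("need at least one labeled pair")
    y = np.array([float(label) for _, label in labeled_pairs])
    if env is None:
        rbar_fixed = np.array([
            float(teacher._rbar(left, right, None))
            for (left, right), _ in labeled_pairs
        ])
    else:
        rng = rng or np.random.default_rng()
        angles = np.array([float(a) for a, _ in labeled_pairs])
    w, b = teacher.readout.w, teacher.readout.b
    for _ in range(steps):
        if env is None:
            rbar = rbar_fixed
        else:
            left, right = env.magnitudes(angles, 0.0, None, rng)
            rbar = teacher._rbar(left, right, rng)
        rho = 1.0 / (1.0 + np.exp(-(w * rbar + b)))
        err = rho - y  # d BCE / d logit
        grad_w = float(np.mean(err * rbar))
        grad_b = float(np.mean(err))
        if not (np.isfinite(grad_w) and np.isfinite(grad_b)):
            raise FloatingPointError("non-finite recalibration gradient")
        w -= lr * grad_w
        b -= lr * grad_b
    teacher.readout.w = w
    teacher.readout.b = b
    return teacher.readout


def inject_bias(teacher: PopulationTeacher, env, beta: float) -> PopulationTeacher:
    """Shift the readout offset so the 0.5 crossing sits at azimuth ``beta``.

    Uses the deterministic population rate at ``beta`` under noiseless
    rendering: the crossing of rho is where w*rbar + b = 0, so setting
    b = -w * rbar(beta) places it exactly at ``beta`` up to member noise.
    """
    left, right = env.magnitudes(float(beta), 0.0, env.level, None)
    rbar = float(teacher._rbar(left, right, None))
    teacher.readout.b = -teacher.readout.w * rbar
    return teacher
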