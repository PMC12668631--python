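import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bootstraphear as bh
from bootstraphear.teacher import (LSOParams, MidlineTeacher,
                                   PopulationTeacher, ReadoutParams,
                                   SingleLSOTeacher, estimate_teacher_stats,
                                   lso_mean_rate, lso_std, monaural_response,
                                   recalibrate_readout, sample_lso_rate,
                                   sample_lso_spike)

P = LSOParams(a=10.0, b=80.0, c=5.0, d=3.0, g=1.0, h=0.5, cf=2000.0)


# ----------------------------------------------------------------------
# single-neuron rate model
# ----------------------------------------------------------------------

def test_mean_rate_closed_form():
    assert lso_mean_rate(P.c, P) == pytest.approx(P.a + P.b / 2)
    assert lso_mean_rate(8.0, P) == pytest.approx(10.0 + 80.0 / (1 + np.exp(-1.0)))
    assert lso_mean_rate(1e3, P) == pytest.approx(P.a + P.b)
    assert lso_mean_rate(-1e3, P) == pytest.approx(P.a)


@settings(deadline=None, max_examples=60)
@given(st.floats(-40, 40), st.floats(0.1, 40))
def test_mean_rate_strictly_increasing(x, dx):
    assert lso_mean_rate(x + dx, P) > lso_mean_rate(x, P)


def test_std_power_law():
    assert lso_std(0.0, P) == 0.0
    assert lso_std(-4.0, LSOParams(10, 80, 5, 3, g=1.0, h=0.5, cf=100)) \
        == pytest.approx(2.0)
    assert lso_std(17.0, LSOParams(10, 80, 5, 3, g=0.0, h=0.5, cf=100)) == 0.0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        LSOParams(10, -1.0, 0, 1, 1, 0.5, 100)
    with pytest.raises(ValueError):
        LSOParams(10, 80, 0, 0.0, 1, 0.5, 100)


def test_noiseless_spike_saturation(rng):
    quiet = LSOParams(10, 80, 5, 3, g=0.0, h=0.5, cf=100)
    high = sample_lso_spike(np.full(200, 1000.0), quiet, rng)
    low = sample_lso_spike(np.full(200, -1000.0), quiet, rng)
    assert np.all(high.spike == 1.0) and np.all(high.rate == 1.0)
    assert np.all(low.spike == 0.0) and np.all(low.rate == 0.0)


def test_spike_frequency_matches_clipped_gaussian_oracle(rng):
    """Empirical spike rate equals E[clip(Norm(N(mu, sigma)))] by Monte Carlo."""
    x = 4.0
    n = 100_000
    out = sample_lso_spike(np.full(n, x), P, rng)
    # independent oracle: direct Monte-Carlo of the clipped-Gaussian mean
    oracle_rng = np.random.default_rng(99)
    draws = oracle_rng.normal(lso_mean_rate(x, P), lso_std(x, P), n)
    expect = np.clip((draws - P.a) / P.b, 0.0, 1.0).mean()
    se = np.sqrt(expect * (1 - expect) / n) + np.std(draws / P.b) / np.sqrt(n)
    assert abs(out.spike.mean() - expect) < 3 * se + 3e-3


def test_rates_always_in_unit_interval(rng):
    x = rng.uniform(-60, 60, 1000)
    r = sample_lso_rate(x, P, rng)
    assert np.all((r >= 0) & (r <= 1))


def test_mirror_antisymmetry(lso_table, env):
    """A right-side neuron at ILD x behaves as the left-side one at -x."""
    left_n = SingleLSOTeacher(lso_table, cf=2000.0, side="left")
    right_n = SingleLSOTeacher(lso_table, cf=2000.0, side="right")
    lm, rm = env.magnitudes(np.array([25.0, -40.0, 5.0]), 0.0, 70.0, None)
    np.testing.assert_allclose(right_n.ild(lm, rm), -left_n.ild(lm, rm))


# ----------------------------------------------------------------------
# population circuit
# ----------------------------------------------------------------------

def test_readout_logistic_values():
    r = ReadoutParams()  # (10, -5)
    assert r.probability(0.5) == pytest.approx(0.5)
    assert r.probability(1.0) == pytest.approx(1.0 / (1.0 + np.exp(-5.0)))
    assert r.probability(0.0) == pytest.approx(1.0 / (1.0 + np.exp(5.0)))


def test_population_saturates_high(env, lso_table, rng):
    """All members noiseless and saturated -> rbar = 1."""
    table = lso_table.copy()
    table["g"] = 0.0
    table["c"] = -500.0  # saturated high at any achievable ILD
    teacher = PopulationTeacher(table, side="right")
    lm, rm = env.magnitudes(0.0, 0.0, 70.0, None)
    assert teacher._rbar(lm, rm, rng) == pytest.approx(1.0)
    assert teacher.mean_rate(lm, rm) == pytest.approx(
        1.0 / (1.0 + np.exp(-5.0)))


def test_empty_population_rejected(lso_table):
    with pytest.raises(ValueError):
        PopulationTeacher(lso_table.iloc[:0], side="right")


def test_population_functional_form(env, lso_table, rng):
    lm, rm = env.magnitudes(30.0, 0.0, 70.0, None)
    out = bh.population_teacher(lm, rm, lso_table, ReadoutParams(), rng)
    assert out.spike in (0.0, 1.0)
    assert 0.0 <= out.rate <= 1.0


# ----------------------------------------------------------------------
# midline detector
# ----------------------------------------------------------------------

def test_midline_detector_prefers_alignment(env, lso_table, rng):
    m = MidlineTeacher.from_table(lso_table)
    lm, rm = env.magnitudes(np.array([0.0, 90.0, -90.0]), 0.0, 70.0, None)
    r = m.mean_rate(lm, rm)
    # normalized peak at alignment, substantially lower laterally (the
    # detector is broadly tuned: low-cf members carry little ILD)
    assert r[0] > 0.95
    assert r[1] < r[0] - 0.3 and r[2] < r[0] - 0.3


def test_midline_product_annihilator(lso_table, rng):
    m = MidlineTeacher.from_table(lso_table)
    # force one side silent: all-left energy drives the right population
    # to its floor and the product (hence the rate) to ~0
    left = np.full(24, 90.0)
    right = np.full(24, 30.0)
    assert m.mean_rate(left, right) < 0.05


def test_midline_tuning_peaks_at_zero(env, lso_table):
    """Grid argmax of the mean response within +-3 deg of the midline."""
    m = MidlineTeacher.from_table(lso_table)
    grid = np.arange(-30.0, 31.0, 1.0)
    lm, rm = env.magnitudes(grid, 0.0, 70.0, None)
    curve = m.mean_rate(lm, rm)
    assert abs(grid[np.argmax(curve)]) <= 3.0
    assert np.all(curve <= 1.0) and np.all(curve >= 0.0)


# ----------------------------------------------------------------------
# monaural response
# ----------------------------------------------------------------------

def test_monaural_response_is_band_mean():
    mags = np.arange(1.0, 25.0)
    assert monaural_response(np.zeros(24), mags, "right") == pytest.approx(12.5)
    assert monaural_response(np.full(24, 7.0), mags, "left") == pytest.approx(7.0)


def test_monaural_right_louder_near_right_ear(env):
    """A source near the right ear beats its mirrored position."""
    lm, rm = env.magnitudes(np.array([60.0, -60.0]), 0.0, 70.0, None)
    right = monaural_response(lm, rm, "right")
    assert right[0] > right[1]


# ----------------------------------------------------------------------
# characterisation
# ----------------------------------------------------------------------

class _AngleEnv:
    """Stub environment whose left magnitudes encode the azimuth directly."""

    level = 70.0

    def magnitudes(self, az, el=0.0, level=None, rng=None):
        az = np.asarray(az, dtype=float)
        return (np.repeat(az[..., None], 24, axis=-1),
                np.zeros(az.shape + (24,)))


class _LogisticTeacher:
    """Spike probability logistic((theta - beta)/k), read from the stub env."""

    def __init__(self, beta, k=4.0):
        self.beta, self.k = beta, k

    def response(self, left, right, rng):
        theta = np.asarray(left)[..., 0]
        rate = 1.0 / (1.0 + np.exp(-(theta - self.beta) / self.k))
        return bh.TeacherOutput(spike=(rng.random(rate.shape) < rate
                                       ).astype(float), rate=rate)


class _StepTeacher:
    def response(self, left, right, rng):
        theta = np.asarray(left)[..., 0]
        rate = (theta > 0).astype(float)
        return bh.TeacherOutput(spike=rate.copy(), rate=rate)


def test_bias_of_constructed_logistic_curve():
    stats = estimate_teacher_stats(
        _LogisticTeacher(beta=7.0), _AngleEnv(),
        np.arange(-40.0, 41.0, 1.0), n_samples=400,
        rng=np.random.default_rng(0))
    assert stats.bias_defined
    assert stats.bias == pytest.approx(7.0, abs=1.0)
    # Bernoulli variance is maximal at the decision boundary
    assert abs(stats.variance_argmax - 7.0) <= 5.0
    assert stats.variance.max() <= 0.25


def test_ideal_step_teacher_has_zero_bias():
    stats = estimate_teacher_stats(
        _StepTeacher(), _AngleEnv(), np.arange(-20.0, 21.0, 1.0),
        n_samples=5, rng=np.random.default_rng(0))
    assert stats.bias == pytest.approx(0.0, abs=1.0)


def test_bias_undefined_when_curve_never_crosses():
    class Always:
        def response(self, left, right, rng):
            r = np.ones(np.asarray(left).shape[:-1])
            return bh.TeacherOutput(spike=r.copy(), rate=r)

    stats = estimate_teacher_stats(Always(), _AngleEnv(),
                                   np.arange(-10.0, 11.0, 1.0), n_samples=3,
                                   rng=np.random.default_rng(0))
    assert not stats.bias_defined and np.isnan(stats.bias)


def test_variance_bound_holds_for_real_teachers(env, pop_teacher):
    stats = estimate_teacher_stats(pop_teacher, env,
                                   np.arange(-30.0, 31.0, 5.0),
                                   n_samples=60,
                                   rng=np.random.default_rng(3))
    assert stats.variance.max() <= 0.25


# ----------------------------------------------------------------------
# readout plasticity
# ----------------------------------------------------------------------

def test_recalibration_gradient_matches_finite_differences(env, lso_table):
    """One descent step equals the numerical BCE gradient."""
    teacher = PopulationTeacher(lso_table, side="right")
    rng = np.random.default_rng(5)
    mags = env.magnitudes(6.0, 0.0, 70.0, rng)
    pairs = [(mags, 1.0)]
    rbar = float(teacher._rbar(*mags, None))

    def bce(w, b):
        rho = 1.0 / (1.0 + np.exp(-(w * rbar + b)))
        return -np.log(rho)

    h = 1e-6
    gw = (bce(10.0 + h, -5.0) - bce(10.0 - h, -5.0)) / (2 * h)
    gb = (bce(10.0, -5.0 + h) - bce(10.0, -5.0 - h)) / (2 * h)
    lr = 0.1
    recalibrate_readout(teacher, pairs, steps=1, lr=lr)
    assert teacher.readout.w == pytest.approx(10.0 - lr * gw, abs=1e-8)
    assert teacher.readout.b == pytest.approx(-5.0 - lr * gb, abs=1e-8)


def test_recalibration_descends_on_satisfied_objective(env, lso_table):
    teacher = PopulationTeacher(lso_table, side="right")
    rng = np.random.default_rng(6)
    pairs = [(env.magnitudes(-8.0, 0.0, 70.0, rng), 0.0),
             (env.magnitudes(8.0, 0.0, 70.0, rng), 1.0)]

    def loss():
        total = 0.0
        for (lm, rm), y in pairs:
            rho = teacher.mean_rate(lm, rm)
            total += -(y * np.log(rho) + (1 - y) * np.log(1 - rho))
        return total / len(pairs)

    losses = [loss()]
    for _ in range(5):
        recalibrate_readout(teacher, pairs, steps=50, lr=0.3)
        losses.append(loss())
    assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


def test_recalibration_requires_pairs(pop_teacher):
    with pytest.raises(ValueError):
        recalibrate_readout(pop_teacher, [], steps=1)


def test_param_table_loader_roundtrip(tmp_path, lso_table):
    path = tmp_path / "params.csv"
    lso_table.to_csv(path, index=False)
    loaded = bh.load_lso_table(path)
    pd.testing.assert_frame_equal(loaded, lso_table)
    with pytest.raises(ValueError):
        bh.load_lso_table(_write_bad_table(tmp_path))


def _write_bad_table(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"a": [1.0], "b": [2.0]}).to_csv(path, index=False)
    return path
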