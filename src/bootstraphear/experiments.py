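"""Reproduction harness: teacher characterisation, training runs, sweeps.

Every experiment is a pure function of (configuration, seed): evaluation
stimuli use a dedicated fixed seed, training uses seeds derived from the
master seed by component name, and re-running writes byte-identical CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .environment import Environment
from .learning import (PolicyConfig, TrainConfig, grid_signed_errors,
                       train_bootstrap, train_policy)
from .student import StudentNet, init_acoustic_student
from .synthetic import child_seed, make_lso_table
from .teacher import (MidlineTeacher, PopulationTeacher, SingleLSOTeacher,
                      estimate_teacher_stats, inject_bias,
                      recalibrate_readout)

EVAL_SEED = 12345


@dataclass
class EvalReport:
    """Per-position localization errors of a Student on a uniform grid."""

    grid: np.ndarray
    signed_errors: np.ndarray  # wrap(yhat - ytrue), degrees

    @property
    def mae(self) -> float:
        return float(np.abs(self.signed_errors).mean())

    @property
    def bias(self) -> float:
        """Mean signed error (positive = clockwise predictions)."""
        return float(self.signed_errors.mean())

    @property
    def std(self) -> float:
        return float(self.signed_errors.std())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle": self.grid,
                             "signed_error": self.signed_errors,
                             "abs_error": np.abs(self.signed_errors)})


def evaluate_student(net: StudentNet, env: Environment, grid=None,
                     eval_seed: int = EVAL_SEED) -> EvalReport:
    """Deterministic evaluation on the 5-degree test grid (72 positions)."""
    if grid is None:
        grid = np.arange(-180.0, 180.0, 5.0)
    grid = np.asarray(grid, dtype=float)
    errors = grid_signed_errors(net, env, grid, eval_seed=eval_seed)
    return EvalReport(grid=grid, signed_errors=errors)


def bootstrap_student(env: Environment, teacher, cfg: TrainConfig,
                      net: StudentNet | None = None):
    """Train a fresh (or given) Student with Algorithm 1; returns (net, curve)."""
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = init_acoustic_student(rng, input_dim=env.input_dim)
    return train_bootstrap(env, teacher, net, cfg, rng)


# ----------------------------------------------------------------------
# Teacher-bias sweep
# ----------------------------------------------------------------------

@dataclass
class SweepResult:
    """Paired teacher bias and student test error across a teacher sweep."""

    table: pd.DataFrame  # columns: teacher, bias, signed_error, inherited, mae, converged

    @property
    def slope(self) -> float:
        """Least-squares slope of the inherited offset on teacher bias.

        NaN when fewer than two converged runs are available.
        """
        ok = self.table["converged"] & np.isfinite(self.table["bias"])
        x = self.table.loc[ok, "bias"].to_numpy()
        y = self.table.loc[ok, "inherited"].to_numpy()
        if x.size < 2 or np.ptp(x) == 0:
            return float("nan")
        return float(np.polyfit(x, y, 1)[0])


def run_bias_sweep(teachers, env: Environment, cfg: TrainConfig,
                   stats_grid=None, stats_samples: int = 10,
                   repetitions: int = 1, convergence_mae: float = 30.0
                   ) -> SweepResult:
    """Characterise each teacher's bias and train a Student per teacher.

    ``teachers`` maps labels to teacher circuits.  The reported
    ``inherited`` offset is -mean signed error: a teacher whose decision
    boundary crosses 0.5 at azimuth beta drives the student to the
    equilibrium yhat = ytrue - beta, so the inherited offset recovers beta
    with slope +1 (the teacher-bias/student-error relationship).
    """
    if stats_grid is None:
        stats_grid = np.arange(-90.0, 91.0, 5.0)
    rows = []
    for label, teacher in teachers.items():
        stats = estimate_teacher_stats(
            teacher, env, stats_grid, n_samples=stats_samples,
            rng=np.random.default_rng(child_seed(cfg.seed, f"stats:{label}")))
        for rep in range(repetitions):
            run_cfg = replace(cfg, seed=child_seed(
                cfg.seed, f"train:{label}:{rep}"))
            net, _ = bootstrap_student(env, teacher, run_cfg)
            report = evaluate_student(net, env)
            rows.append({
                "teacher": label, "repetition": rep, "bias": stats.bias,
                "signed_error": report.bias, "inherited": -report.bias,
                "mae": report.mae,
                "converged": report.mae < convergence_mae,
            })
    return SweepResult(table=pd.DataFrame(rows))


def single_lso_sweep_teachers(param_table: pd.DataFrame | None = None,
                              seed: int = 0):
    """The 32 single-neuron teachers of the bias sweep, keyed by row index."""
    if param_table is None:
        param_table = make_lso_table(32, seed=seed)
    return {
        f"lso{j}": SingleLSOTeacher(param_table.iloc[[j]],
                                    cf=float(param_table.iloc[j]["cf"]))
        for j in range(len(param_table))
    }


def injected_bias_teachers(env: Environment, betas,
                           param_table: pd.DataFrame | None = None,
                           seed: int = 0):
    """Population teachers with the readout offset shifted to given biases."""
    if param_table is None:
        param_table = make_lso_table(32, seed=seed)
    teachers = {}
    for beta in betas:
        t = PopulationTeacher(param_table, side="right")
        inject_bias(t, env, float(beta))
        teachers[f"beta{beta:+.0f}"] = t
    return teachers


# ----------------------------------------------------------------------
# Cue disruption and recalibration
# ----------------------------------------------------------------------

def run_disruption_experiment(spec, env: Environment, teacher_table,
                              cfg: TrainConfig,
                              recalibrate: str = "none",
                              pretrained: StudentNet | None = None,
                              stats_samples: int = 100,
                              recal_steps: int = 1000,
                              recal_lr: float = 0.3):
    """Disrupt the cues, measure teacher and student, optionally recalibrate.

    ``recalibrate``:
      * ``"none"``               — measure the disrupted system only.
      * ``"student_only"``       — bootstrap-retrain the Student with the
                                   (possibly biased) non-plastic Teacher.
      * ``"teacher_then_student"`` — first recalibrate the Teacher readout
        with two binary-labeled stimuli in [-10, 10] (one per side), then
        retrain the Student with the recalibrated Teacher.

    Returns a dict of :class:`EvalReport`/TeacherStats before/after.
    """
    if recalibrate not in ("none", "student_only", "teacher_then_student"):
        raise ValueError(f"unknown recalibration mode {recalibrate!r}")
    results = {}
    teacher = PopulationTeacher(teacher_table, side="right")
    stats_rng = np.random.default_rng(child_seed(cfg.seed, "disrupt-stats"))
    results["teacher_before"] = estimate_teacher_stats(
        teacher, env, n_samples=stats_samples, rng=stats_rng)
    if pretrained is None:
        pretrained, _ = bootstrap_student(env, teacher, cfg)
    results["student_before"] = evaluate_student(pretrained, env)

    disrupted = env.with_disruption(spec)
    results["teacher_disrupted"] = estimate_teacher_stats(
        teacher, disrupted, n_samples=stats_samples,
        rng=np.random.default_rng(child_seed(cfg.seed, "disrupt-stats2")))
    results["student_disrupted"] = evaluate_student(pretrained, disrupted)

    if recalibrate == "none":
        return results

    if recalibrate == "teacher_then_student":
        # the members' dynamic range first adapts (unsupervised) to the
        # disrupted input statistics, then the readout is recalibrated
        # from two binary-labeled stimuli near the midline
        teacher.adapt_normalization(disrupted)
        rng = np.random.default_rng(child_seed(cfg.seed, "recal-labels"))
        pairs = two_label_angles(rng)
        recalibrate_readout(teacher, pairs, steps=recal_steps, lr=recal_lr,
                            env=disrupted, rng=rng)
        results["teacher_recalibrated"] = estimate_teacher_stats(
            teacher, disrupted, n_samples=stats_samples,
            rng=np.random.default_rng(child_seed(cfg.seed, "disrupt-stats3")))

    retrain_cfg = replace(cfg, seed=child_seed(cfg.seed, "disrupt-retrain"))
    net = pretrained.copy()
    net, _ = train_bootstrap(disrupted, teacher, net, retrain_cfg,
                             np.random.default_rng(retrain_cfg.seed))
    results["student_recalibrated"] = evaluate_student(net, disrupted)
    return results


def two_label_angles(rng: np.random.Generator, half_range: float = 10.0):
    """Two binary-labeled source angles near the midline, one per side.

    The teacher readout is recalibrated as a left/right classifier from two
    labeled sound samples within +-10 degrees; one angle is drawn on each
    side so both classes are represented (two same-side samples would leave
    the boundary unconstrained).
    """
    return [(float(rng.uniform(-half_range, 0.0)), 0.0),
            (float(rng.uniform(0.0, half_range)), 1.0)]


def two_label_pairs(env: Environment, rng: np.random.Generator,
                    half_range: float = 10.0):
    """Fixed-stimulus variant of :func:`two_label_angles` (rendered once)."""
    pairs = []
    for theta, label in two_label_angles(rng, half_range):
        mags = env.magnitudes(theta, 0.0, env.level, rng)
        pairs.append((mags, label))
    return pairs


# ----------------------------------------------------------------------
# Reinforcement learning
# ----------------------------------------------------------------------

def run_rl_experiment(env: Environment, cfg: PolicyConfig,
                      teacher_table=None, noise_scale: float = 1.0):
    """Train a Gaussian-policy Student with the midline-detector reward.

    Returns ``(net, curve, report)``; the report evaluates at 5-degree
    intervals over the frontal semicircle.
    """
    if teacher_table is None:
        teacher_table = make_lso_table(32, seed=child_seed(cfg.seed, "lso"))
    teacher = MidlineTeacher.from_table(teacher_table, noise_scale=noise_scale)
    rng = np.random.default_rng(cfg.seed)
    net = init_acoustic_student(rng, input_dim=env.input_dim)
    net, curve = train_policy(env, teacher, net, cfg, rng)
    grid = np.arange(-90.0, 91.0, 5.0)
    report = evaluate_student(net, env, grid)
    return net, curve, report


# ----------------------------------------------------------------------
# Output helpers
# ----------------------------------------------------------------------

def write_curve(path, curve, seed: int) -> None:
    rows = [dict(zip(("step", "mae", "mean_return"), c)) for c in curve]
    frame = pd.DataFrame(rows)
    frame["seed"] = seed
    frame.to_csv(path, index=False)


def write_manifest(path, config: dict) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
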