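"""Closed-loop validation, training-size convergence, and between-set comparison.

The round-trip check: for each held-out trial, predict capsule parameters
from its laxity subset and PC scores, rebuild the capsule mesh from the true
scores, re-simulate the full 40-metric profile, and score the RMSE against
the trial's original laxity.  Per-trial RMSEs feed Student's t-tests between
training-set variants and the training-size convergence curve (<5% change in
composite RMSE between successive sizes counts as converged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .geometry import build_capsule_mesh
from .mechanics import evaluate_laxity_profile
from .regression import (
    TRAINING_SETS,
    RegressionModel,
    TrainingSetSpec,
    predict_parameters,
    train_surrogate,
)
from .sampling import MeshConfig, TrialRecord, generate_trial_dataset
from .ssm import ShapeModel, fit_shape_model, reconstruct_attachments

__all__ = [
    "ValidationReport",
    "SetComparison",
    "ConvergenceResult",
    "closed_loop_validate",
    "convergence_study",
    "compare_sets",
    "run_baseline_study",
]

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """Closed-loop RMSE summary for one trained surrogate."""

    per_trial_rmse: np.ndarray  # deg, one per successfully re-simulated trial
    per_metric_rmse: np.ndarray  # deg, one per laxity metric (across trials)
    metric_names: list
    set_id: int
    n_train: int
    n_failed: int = 0

    @property
    def composite_mean(self) -> float:
        return float(np.mean(self.per_trial_rmse))

    @property
    def composite_sd(self) -> float:
        return float(np.std(self.per_trial_rmse, ddof=1))


@dataclass
class SetComparison:
    """Pairwise Student's t-tests between per-trial RMSE samples."""

    set_ids: list
    t_statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05
    paired: bool = False


@dataclass
class ConvergenceResult:
    sizes: list
    composite_rmse: list
    converged: bool
    threshold: float = 0.05


def closed_loop_validate(
    model: RegressionModel,
    validation_trials: Sequence[TrialRecord],
    shape_model: ShapeModel,
    mesh_config: MeshConfig | None = None,
) -> ValidationReport:
    """Predict -> re-simulate -> RMSE over all 40 metrics for held-out trials.

    Trials whose re-simulation fails to converge are excluded from the
    aggregates; the count is recorded in ``n_failed``.
    """
    mesh_config = mesh_config or MeshConfig()
    trials = [t for t in validation_trials if t.ok and t.laxity is not None]
    per_trial = []
    sq_err_by_metric = []
    n_failed = 0
    metric_names = None
    for rec in trials:
        try:
            predicted = predict_parameters(model, rec.laxity, rec.scores, clip=True)
            ace, fem = reconstruct_attachments(shape_model, rec.scores)
            mesh = build_capsule_mesh(ace, fem, mesh_config.sphere, mesh_config.n_lines)
            resim = evaluate_laxity_profile(mesh, predicted, frame=mesh_config.frame)
        except Exception as err:  # noqa: BLE001
            logger.warning("validation trial %d failed: %s", rec.trial_id, err)
            n_failed += 1
            continue
        err_vec = resim.rotations - rec.laxity.rotations
        per_trial.append(float(np.sqrt(np.mean(err_vec**2))))
        sq_err_by_metric.append(err_vec**2)
        metric_names = resim.metric_names()
    if not per_trial:
        raise RuntimeError("no validation trial could be re-simulated")
    return ValidationReport(
        per_trial_rmse=np.array(per_trial),
        per_metric_rmse=np.sqrt(np.mean(np.array(sq_err_by_metric), axis=0)),
        metric_names=metric_names,
        set_id=model.set_id,
        n_train=model.metadata.get("n_trials", -1),
        n_failed=n_failed,
    )


def convergence_study(
    dataset: Sequence[TrialRecord],
    spec: TrainingSetSpec,
    shape_model: ShapeModel,
    sizes: Sequence[int] = (100, 200, 300, 400, 450),
    seed: int = 0,
    mesh_config: MeshConfig | None = None,
    holdout: int = 50,
    threshold: float = 0.05,
) -> ConvergenceResult:
    """Composite RMSE versus training-set size on a fixed holdout.

    The dataset is shuffled once by ``seed``; the last ``holdout`` complete
    trials form the fixed validation set and training subsets are nested
    (each size extends the previous one).
    """
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    complete = [t for t in dataset if t.ok and t.laxity is not None]
    if sizes[-1] + holdout > len(complete):
        raise ValueError("dataset too small for the requested sizes plus holdout")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(complete))
    shuffled = [complete[i] for i in order]
    val = shuffled[-holdout:]
    pool = shuffled[:-holdout]

    rmses = []
    for size in sizes:
        model = train_surrogate(pool[:size], spec)
        report = closed_loop_validate(model, val, shape_model, mesh_config)
        rmses.append(report.composite_mean)
        logger.info("size %d: composite RMSE %.3f deg", size, rmses[-1])
    converged = (
        len(rmses) >= 2 and abs(rmses[-1] - rmses[-2]) / max(abs(rmses[-2]), 1e-12) < threshold
    )
    return ConvergenceResult(
        sizes=sizes, composite_rmse=rmses, converged=converged, threshold=threshold
    )


def run_baseline_study(
    seed: int = 0,
    n_trials: int = 500,
    n_train: int = 450,
    holdout: int = 50,
    set_id: int = 1,
    n_subjects: int = 150,
    mesh_config: MeshConfig | None = None,
) -> ValidationReport:
    """The full calibration study: population → trials → surrogate → closed loop.

    Builds a synthetic attachment population and its 4-mode shape model,
    generates the probabilistic trial dataset by Latin hypercube sampling,
    trains the requested training-set surrogate on ``n_train`` trials, and
    closed-loop validates it on the ``holdout`` remaining trials.
    """
    from .synthetic import PopulationConfig, synthetic_attachment_population

    population = synthetic_attachment_population(
        PopulationConfig(n_subjects=n_subjects, seed=seed + 1)
    )
    shape_model = fit_shape_model(population, n_modes=4)
    records = generate_trial_dataset(
        n_trials, shape_model, mesh_config=mesh_config, seed=seed + 2
    )
    complete = [r for r in records if r.ok]
    rng = np.random.default_rng(seed + 3)
    order = rng.permutation(len(complete))
    shuffled = [complete[i] for i in order]
    if len(shuffled) < n_train + 2:
        raise RuntimeError("too many failed trials to form the requested split")
    train = shuffled[:n_train]
    val = shuffled[n_train : n_train + holdout]
    model = train_surrogate(train, TRAINING_SETS[set_id])
    return closed_loop_validate(model, val, shape_model, mesh_config)


def compare_sets(
    reports: Sequence[ValidationReport], alpha: float = 0.05, paired: bool = False
) -> SetComparison:
    """Pairwise Student's t-tests (equal-variance, two-sided) on per-trial RMSEs."""
    if len(reports) < 2:
        raise ValueError("compare_sets requires at least two reports")
    for rep in reports:
        if len(rep.per_trial_rmse) < 2:
            raise ValueError("each report needs at least two per-trial RMSE samples")
    m = len(reports)
    tmat = np.zeros((m, m))
    pmat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = reports[i].per_trial_rmse, reports[j].per_trial_rmse
            if paired:
                res = stats.ttest_rel(a, b)
            else:
                res = stats.ttest_ind(a, b, equal_var=True)
            tmat[i, j] = tmat[j, i] = float(res.statistic)
            pmat[i, j] = pmat[j, i] = float(res.pvalue)
    return SetComparison(
        set_ids=[rep.set_id for rep in reports],
        t_statistic=tmat,
        p_value=pmat,
        significant=pmat < alpha,
        alpha=alpha,
        paired=paired,
    )
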