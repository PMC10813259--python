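"""Stepwise multilinear surrogate mapping laxity + shape scores to capsule parameters.

Each of the 12 capsule mechanical properties gets its own multilinear model

    p_k = b0 + sum_i l_i * L_i + sum_i p_i * PC_i

with terms chosen by forward/backward stepwise selection on partial F-test
p-values (enter at p < 0.05, remove at p > 0.10 by default).  The candidate
laxity subset is one of nine registered training sets differing in rotation
families (I-E, Ad-Ab) and flexion angles; all sets keep both the 1 Nm and
5 Nm readings and all four PC scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .mechanics import CapsuleParameters, LaxityProfile
from .sampling import PARAMETER_NAMES, TrialRecord

__all__ = [
    "TrainingSetSpec",
    "TRAINING_SETS",
    "RegressionModel",
    "stepwise_fit",
    "train_surrogate",
    "predict_parameters",
    "RankDeficiencyError",
    "MissingPredictorError",
]

OUTPUT_NAMES = PARAMETER_NAMES[:12]
PC_NAMES = PARAMETER_NAMES[12:]


class RankDeficiencyError(ValueError):
    """Selected design matrix is rank-deficient."""


class MissingPredictorError(KeyError):
    """A predictor required by the model was not supplied."""


@dataclass(frozen=True)
class TrainingSetSpec:
    """One row of the training-set registry.

    ``families`` lists included rotation families: "IE" covers the internal
    and external directions, "AdAb" covers adduction and abduction.  Both
    torque levels are always kept.
    """

    set_id: int
    families: tuple
    flexions: tuple
    torques: tuple = (1.0, 5.0)

    _FAMILY_DIRECTIONS = {"IE": ("internal", "external"), "AdAb": ("abduction", "adduction")}

    @property
    def directions(self) -> tuple:
        return tuple(d for fam in self.families for d in self._FAMILY_DIRECTIONS[fam])

    @property
    def n_laxity(self) -> int:
        return len(self.directions) * len(self.flexions) * len(self.torques)

    @property
    def laxity_names(self) -> list[str]:
        return [
            f"{d}_{f}_{t:g}Nm"
            for d in self.directions
            for f in self.flexions
            for t in self.torques
        ]

    @property
    def predictor_names(self) -> list[str]:
        return self.laxity_names + list(PC_NAMES)


TRAINING_SETS: dict[int, TrainingSetSpec] = {
    1: TrainingSetSpec(1, ("IE", "AdAb"), (0, 30, 60, 90)),
    2: TrainingSetSpec(2, ("IE",), (0, 30, 60, 90)),
    3: TrainingSetSpec(3, ("AdAb",), (0, 30, 60, 90)),
    4: TrainingSetSpec(4, ("IE", "AdAb"), (0, 45, 90)),
    5: TrainingSetSpec(5, ("IE",), (0, 45, 90)),
    6: TrainingSetSpec(6, ("AdAb",), (0, 45, 90)),
    7: TrainingSetSpec(7, ("IE", "AdAb"), (0, 90)),
    8: TrainingSetSpec(8, ("IE",), (0, 90)),
    9: TrainingSetSpec(9, ("AdAb",), (0, 90)),
}


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """OLS with intercept: (coefs with intercept first, RSS, residual dof)."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    k = design.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k:
        raise RankDeficiencyError("design matrix is rank-deficient")
    dof = n - k
    if dof <= 0:
        raise RankDeficiencyError("not enough rows for the selected terms")
    resid = y - design @ coef
    return coef, float(resid @ resid), dof


def _partial_f_pvalue(rss_small: float, rss_large: float, dof_large: int, tol: float) -> float:
    """p-value of the 1-df partial F-test comparing nested OLS fits.

    A numerically perfect fit (RSS below ``tol``) is handled explicitly so a
    zero-residual model neither attracts nor retains noise terms.
    """
    gain = rss_small - rss_large
    if gain <= tol:
        return 1.0
    if rss_large <= tol:
        return 0.0
    f = gain / (rss_large / dof_large)
    return float(stats.f.sf(f, 1, dof_large))


@dataclass
class StepwiseResult:
    selected: list[int]
    coef: np.ndarray  # aligned with `selected`
    intercept: float
    residuals: np.ndarray
    n_obs: int


def stepwise_fit(
    X: np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward/backward stepwise linear regression with partial F/t tests.

    Starting from the intercept-only model, repeatedly add the candidate with
    the smallest entry p-value below ``p_enter``, then drop included terms
    whose p-value exceeds ``p_remove``, until neither step changes the model.
    Deterministic given inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("stepwise_fit requires at least 10 rows")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = list(np.flatnonzero(col_sd == 0))
        raise ValueError(f"constant candidate columns are not allowed: {bad}")

    tol = 1e-12 * max(float(y @ y), 1.0)
    selected: list[int] = []
    visited: set[frozenset] = set()
    for _ in range(4 * p + 10):
        changed = False
        # forward step: candidate with the smallest partial-F entry p-value
        _, rss0, _ = _ols(X[:, selected], y)
        best_j, best_p = None, np.inf
        for j in range(p):
            if j in selected:
                continue
            try:
                _, rss1, dof1 = _ols(X[:, selected + [j]], y)
            except RankDeficiencyError:
                continue
            pj = _partial_f_pvalue(rss0, rss1, dof1, tol)
            if pj < best_p:
                best_j, best_p = j, pj
        if best_j is not None and best_p < p_enter:
            selected.append(best_j)
            changed = True
        # backward steps: drop the worst term while its removal p-value exceeds p_remove
        while selected:
            _, rss_full, dof_full = _ols(X[:, selected], y)
            term_p = []
            for i in range(len(selected)):
                reduced = selected[:i] + selected[i + 1 :]
                _, rss_minus, _ = _ols(X[:, reduced], y)
                term_p.append(_partial_f_pvalue(rss_minus, rss_full, dof_full, tol))
            worst = int(np.argmax(term_p))
            if term_p[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        state = frozenset(selected)
        if not changed or state in visited:
            break
        visited.add(state)

    if selected:
        coef, _, _ = _ols(X[:, selected], y)
        intercept, betas = float(coef[0]), coef[1:]
        resid = y - intercept - X[:, selected] @ betas
    else:
        intercept, betas = float(np.mean(y)), np.empty(0)
        resid = y - intercept
    return StepwiseResult(
        selected=list(selected), coef=betas, intercept=intercept, residuals=resid, n_obs=n
    )


@dataclass
class RegressionModel:
    """Per-output stepwise models keyed by capsule parameter name."""

    outputs: dict  # name -> {"terms": [predictor names], "coef": [...], "intercept": float}
    set_id: int
    metadata: dict = field(default_factory=dict)

    @property
    def spec(self) -> TrainingSetSpec:
        return TRAINING_SETS[self.set_id]

    def save_json(self, path) -> None:
        payload = {"outputs": self.outputs, "set_id": self.set_id, "metadata": self.metadata}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            outputs=payload["outputs"],
            set_id=payload["set_id"],
            metadata=payload.get("metadata", {}),
        )


def design_from_records(
    records: Sequence[TrialRecord], spec: TrainingSetSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Predictor matrix, 12-column response matrix, and predictor names."""
    complete = [r for r in records if r.ok and r.laxity is not None]
    names = spec.predictor_names
    X = np.empty((len(complete), len(names)))
    Y = np.empty((len(complete), 12))
    for i, rec in enumerate(complete):
        lax = rec.laxity.as_dict()
        X[i, : spec.n_laxity] = [lax[nm] for nm in spec.laxity_names]
        X[i, spec.n_laxity :] = rec.scores
        Y[i] = rec.params.as_vector()
    return X, Y, names


def train_surrogate(
    dataset: Sequence[TrialRecord],
    spec: TrainingSetSpec,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionModel:
    """Fit 12 independent stepwise models (one per capsule parameter)."""
    complete = [r for r in dataset if r.ok and r.laxity is not None]
    if len(complete) < 50:
        raise ValueError("train_surrogate requires at least 50 complete trials")
    X, Y, names = design_from_records(complete, spec)
    outputs = {}
    for k, out_name in enumerate(OUTPUT_NAMES):
        try:
            res = stepwise_fit(X, Y[:, k], p_enter=p_enter, p_remove=p_remove)
        except (ValueError, RankDeficiencyError) as err:
            raise type(err)(f"output {out_name!r}: {err}") from err
        outputs[out_name] = {
            "terms": [names[j] for j in res.selected],
            "coef": [float(c) for c in res.coef],
            "intercept": res.intercept,
        }
    return RegressionModel(
        outputs=outputs,
        set_id=spec.set_id,
        metadata={
            "n_trials": len(complete),
            "p_enter": p_enter,
            "p_remove": p_remove,
            "n_candidates": len(names),
        },
    )


def predict_parameters(
    model: RegressionModel,
    laxity: LaxityProfile | Mapping[str, float],
    scores: np.ndarray,
    clip: bool = False,
) -> CapsuleParameters:
    """Evaluate the surrogate: capsule parameters from laxity + PC scores.

    ``laxity`` may be a full profile or any mapping that covers the model's
    selected laxity predictors.  A missing predictor raises
    :class:`MissingPredictorError` listing the absent names.  With
    ``clip=True`` predictions are clipped into the sampled population support
    (the surrogate is an interpolator over the probabilistic input domain and
    extrapolated parameters can be unphysical), which is advisable before
    re-simulation.
    """
    lax = laxity.as_dict() if isinstance(laxity, LaxityProfile) else dict(laxity)
    scores = np.asarray(scores, dtype=float)
    values = dict(lax)
    values.update({name: float(s) for name, s in zip(PC_NAMES, scores)})

    missing = sorted(
        {t for spec in model.outputs.values() for t in spec["terms"] if t not in values}
    )
    if missing:
        raise MissingPredictorError(f"missing predictors: {missing}")

    out = np.empty(12)
    for k, name in enumerate(OUTPUT_NAMES):
        spec = model.outputs[name]
        out[k] = spec["intercept"] + sum(
            c * values[t] for c, t in zip(spec["coef"], spec["terms"])
        )
    stiffness, pre_strain = out[:6], out[6:12]
    if clip:
        # union of the per-sector truncated-normal supports (mean ± 1.96 SD)
        stiffness = np.clip(stiffness, 20.0, 100.0)
        pre_strain = np.clip(pre_strain, 0.38, 1.09)
    return CapsuleParameters(stiffness=stiffness, pre_strain=pre_strain)
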