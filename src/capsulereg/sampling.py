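"""Latin-hypercube sampling of capsule inputs and probabilistic trial generation.

The 16 probabilistic inputs are the six sector stiffnesses, six sector
pre-strains, and four attachment-shape PC scores.  Mechanical parameters are
drawn from truncated normals covering 95% of the population (±1.96 SD); PC
scores are truncated standard normals bounded at ±2 SD.  Each trial
reconstructs attachment geometry from its PC scores, builds the spring mesh,
and evaluates the full 40-metric laxity profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AnatomicFrame, build_capsule_mesh
from .mechanics import CapsuleParameters, LaxityProfile, evaluate_laxity_profile
from .ssm import ShapeModel, reconstruct_attachments
from .wrapping import Sphere

__all__ = [
    "ParameterDistributions",
    "MeshConfig",
    "TrialRecord",
    "lhs_normal",
    "generate_trial_dataset",
    "dataset_to_frame",
    "PARAMETER_NAMES",
]

logger = logging.getLogger(__name__)

PARAMETER_NAMES = tuple(
    [f"sector{i}_stiffness" for i in range(1, 7)]
    + [f"sector{i}_prestrain" for i in range(1, 7)]
    + [f"pc{i}" for i in range(1, 5)]
)

# population means / SDs of the capsule mechanical properties (stiffness in
# N/mm, pre-strain dimensionless) and the ±2 SD bounds on shape scores
_DEFAULT_MEANS = np.array(
    [61.0, 62.3, 58.5, 53.9, 70.5, 50.4, 0.99, 0.71, 0.62, 0.57, 0.48, 0.57, 0, 0, 0, 0]
)
_DEFAULT_SDS = np.array([15.0] * 6 + [0.05] * 6 + [1.0] * 4)
_DEFAULT_TRUNC = np.array([1.96] * 12 + [2.0] * 4)


@dataclass(frozen=True)
class ParameterDistributions:
    """Per-parameter normal distributions with symmetric truncation (in SDs)."""

    names: tuple = PARAMETER_NAMES
    mean: np.ndarray = field(default_factory=lambda: _DEFAULT_MEANS.copy())
    sd: np.ndarray = field(default_factory=lambda: _DEFAULT_SDS.copy())
    trunc_z: np.ndarray = field(default_factory=lambda: _DEFAULT_TRUNC.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        object.__setattr__(self, "trunc_z", np.asarray(self.trunc_z, dtype=float))
        n = len(self.names)
        if not (self.mean.shape == self.sd.shape == self.trunc_z.shape == (n,)):
            raise ValueError("mean, sd and trunc_z must match the parameter names")
        if np.any(self.sd <= 0) or np.any(self.trunc_z <= 0):
            raise ValueError("standard deviations and truncation bounds must be positive")

    @classmethod
    def default(cls) -> "ParameterDistributions":
        return cls()

    @property
    def n_parameters(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class MeshConfig:
    """Capsule mesh resolution and femoral-head sphere used in simulation."""

    n_lines: int = 36
    head_radius: float = 22.0
    head_center: tuple = (0.0, 0.0, 0.0)
    frame: AnatomicFrame = field(default_factory=AnatomicFrame)

    @property
    def sphere(self) -> Sphere:
        return Sphere(center=np.asarray(self.head_center, dtype=float), radius=self.head_radius)


@dataclass
class TrialRecord:
    """One probabilistic trial: 16 inputs, 40 laxity outputs, provenance."""

    trial_id: int
    params: CapsuleParameters
    scores: np.ndarray
    laxity: LaxityProfile | None
    ok: bool
    error: str | None
    seed: int

    @property
    def inputs(self) -> np.ndarray:
        return np.concatenate([self.params.as_vector(), self.scores])


def lhs_normal(n: int, dists: ParameterDistributions, seed: int | None = None) -> np.ndarray:
    """Latin hypercube draw of ``n`` samples from truncated normal marginals.

    Each marginal is stratified into ``n`` equal-probability bins of the
    truncated normal (one sample per bin, position within the bin uniform),
    and the inter-column pairing is randomized by the seed.
    """
    if n < 2:
        raise ValueError("lhs_normal requires n >= 2")
    rng = np.random.default_rng(seed)
    p = dists.n_parameters
    out = np.empty((n, p))
    for j in range(p):
        z = dists.trunc_z[j]
        u_lo, u_hi = stats.norm.cdf(-z), stats.norm.cdf(z)
        edges = np.linspace(u_lo, u_hi, n + 1)
        u = rng.uniform(edges[:-1], edges[1:])
        u = rng.permutation(u)
        out[:, j] = dists.mean[j] + dists.sd[j] * stats.norm.ppf(u)
    return out


def generate_trial_dataset(
    n_trials: int,
    model: ShapeModel,
    dists: ParameterDistributions | None = None,
    mesh_config: MeshConfig | None = None,
    seed: int = 0,
) -> list[TrialRecord]:
    """Monte Carlo trial dataset linking the 16 inputs to the 40 laxity metrics.

    Deterministic given the seed.  Trials whose simulation fails are retained
    with ``ok=False`` and the error message rather than dropped.
    """
    dists = dists or ParameterDistributions.default()
    mesh_config = mesh_config or MeshConfig()
    samples = lhs_normal(n_trials, dists, seed)
    records: list[TrialRecord] = []
    for i in range(n_trials):
        row = samples[i]
        params = CapsuleParameters(stiffness=row[:6], pre_strain=row[6:12])
        scores = row[12:16].copy()
        try:
            ace, fem = reconstruct_attachments(model, scores)
            mesh = build_capsule_mesh(ace, fem, mesh_config.sphere, mesh_config.n_lines)
            laxity = evaluate_laxity_profile(mesh, params, frame=mesh_config.frame)
            records.append(TrialRecord(i, params, scores, laxity, True, None, seed))
        except Exception as err:  # noqa: BLE001 - failures are data, not crashes
            logger.warning("trial %d failed: %s", i, err)
            records.append(TrialRecord(i, params, scores, None, False, str(err), seed))
        if (i + 1) % 50 == 0:
            logger.info("simulated %d/%d trials", i + 1, n_trials)
    return records


def dataset_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Wide table: trial_id, ok, 16 input columns, 40 laxity columns."""
    laxity_names = LaxityProfile.metric_names()
    rows = []
    for rec in records:
        row = {"trial_id": rec.trial_id, "ok": rec.ok}
        row.update(dict(zip(PARAMETER_NAMES, map(float, rec.inputs))))
        if rec.laxity is not None:
            row.update(rec.laxity.as_dict())
        else:
            row.update({name: np.nan for name in laxity_names})
        rows.append(row)
    return pd.DataFrame(rows)


def dataset_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`dataset_to_frame` (seed provenance is not stored)."""
    laxity_names = LaxityProfile.metric_names()
    records = []
    for _, row in df.iterrows():
        params = CapsuleParameters(
            stiffness=[row[f"sector{i}_stiffness"] for i in range(1, 7)],
            pre_strain=[row[f"sector{i}_prestrain"] for i in range(1, 7)],
        )
        scores = np.array([row[f"pc{i}"] for i in range(1, 5)])
        ok = bool(row["ok"])
        laxity = (
            LaxityProfile(rotations=np.array([row[n] for n in laxity_names])) if ok else None
        )
        records.append(
            TrialRecord(int(row["trial_id"]), params, scores, laxity, ok, None, seed=-1)
        )
    return records
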