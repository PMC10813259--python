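"""Synthetic attachment populations and synthetic "cadaveric" specimens.

Stands in for a CT-derived anatomical database and for laxity-bench
experiments: a base pair of attachment ellipses is perturbed along four
orthogonal displacement modes (qualitatively: capsule length, femoral
version-like A-P shift, inclination-like lateral shift, acetabular depth)
plus isotropic node noise.  Synthetic specimens draw true capsule parameters
and shape scores from the population distributions, simulate their laxity,
and expose only the experimentally measurable subset (I-E rotation at
0/30/60/90° flexion, 1 and 5 Nm) with additive measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    AnatomicFrame,
    AttachmentNodeSet,
    EllipseSpec,
    build_capsule_mesh,
    resample_ellipse,
)
from .mechanics import CapsuleParameters, LaxityProfile, evaluate_laxity_profile
from .sampling import MeshConfig, ParameterDistributions
from .ssm import ShapeModel, reconstruct_attachments

__all__ = [
    "PopulationConfig",
    "SyntheticSpecimen",
    "default_base_ellipses",
    "synthetic_attachment_population",
    "synthetic_specimen",
]

#: the experimentally measurable laxity subset: I-E at four flexion angles
EXPERIMENT_METRICS = [
    f"{d}_{f}_{t:g}Nm"
    for d in ("internal", "external")
    for f in (0, 30, 60, 90)
    for t in (1.0, 5.0)
]


def default_base_ellipses() -> tuple[EllipseSpec, EllipseSpec]:
    """Plausible mean attachment ellipses in the hip anatomic frame (mm).

    Hip center at the origin; anterior/superior/lateral positive.  The
    acetabular rim ellipse hugs the femoral head with its opening facing
    anterolaterally and slightly inferiorly; the femoral intertrochanteric
    ellipse sits at the lateral base of the neck with a small anteversion,
    so the capsule sleeve is roughly coaxial with the femoral neck.  A
    neck-coaxial sleeve tolerates the full 0–90° flexion arc the way a real
    capsule does (flexion partly twists rather than purely bends it), which
    keeps the torque–rotation response single-welled at deep flexion.
    """
    ace_normal = np.array([0.35, -0.4, 0.85])
    ace = EllipseSpec(
        center=np.array([0.0, 2.0, -3.0]),
        plane_normal=ace_normal / np.linalg.norm(ace_normal),
        major_axis_dir=_in_plane(ace_normal, [1.0, 0.0, 0.0]),
        semi_major=27.0,
        semi_minor=25.5,
    )
    fem_normal = np.array([0.2, -0.55, 0.81])
    fem = EllipseSpec(
        center=np.array([7.0, -27.0, 34.0]),
        plane_normal=fem_normal / np.linalg.norm(fem_normal),
        major_axis_dir=_in_plane(fem_normal, [1.0, 0.0, 0.0]),
        semi_major=30.0,
        semi_minor=24.0,
    )
    return ace, fem


def _in_plane(normal, seed_dir) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    v = np.asarray(seed_dir, dtype=float)
    v = v - (v @ n) * n
    return v / np.linalg.norm(v)


@dataclass
class PopulationConfig:
    """Synthetic population: base ellipses + 4 orthogonal modes + node noise."""

    n_subjects: int = 150
    n_nodes: int = 360
    mode_sds: tuple = (4.0, 3.0, 2.0, 1.0)
    noise_sd: float = 0.1
    seed: int = 0
    frame: AnatomicFrame = field(default_factory=AnatomicFrame)
    base_ellipses: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.mode_sds) != 4:
            raise ValueError("exactly 4 mode SDs are required")
        if any(b > a for a, b in zip(self.mode_sds, self.mode_sds[1:])):
            raise ValueError("mode SDs must be non-increasing")
        if self.base_ellipses is None:
            self.base_ellipses = default_base_ellipses()


def _mode_patterns(config: PopulationConfig, ace_normal: np.ndarray) -> np.ndarray:
    """Four orthonormal displacement fields over the stacked (2n, 3) nodes.

    Modes act on disjoint node blocks / orthogonal directions so mutual
    orthogonality is exact: femoral inferior shift (capsule length), femoral
    anterior shift (version-like), femoral lateral shift (inclination-like),
    and acetabular displacement opposite the rim opening (acetabular depth).
    """
    n = config.n_nodes
    dim = 2 * n * 3
    modes = np.zeros((4, dim))
    fem_block = slice(3 * n, 6 * n)
    for k, direction in enumerate(
        [np.array([0.0, -1.0, 0.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])]
    ):
        pattern = np.tile(direction, n)
        modes[k, fem_block] = pattern / np.linalg.norm(pattern)
    depth = np.tile(-ace_normal, n)
    modes[3, : 3 * n] = depth / np.linalg.norm(depth)
    gram = modes @ modes.T
    if not np.allclose(gram, np.eye(4), atol=1e-9):
        raise ValueError("mode displacement patterns must be orthonormal")
    return modes


def synthetic_attachment_population(
    config: PopulationConfig,
) -> list[tuple[AttachmentNodeSet, AttachmentNodeSet]]:
    """Deterministic (by seed) population of paired attachment loops."""
    if config.n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    ace_ellipse, fem_ellipse = config.base_ellipses
    ace = resample_ellipse(ace_ellipse, config.n_nodes, config.frame, side="acetabular")
    fem = resample_ellipse(fem_ellipse, config.n_nodes, config.frame, side="femoral")
    base = np.concatenate([ace.nodes.ravel(), fem.nodes.ravel()])
    modes = _mode_patterns(config, ace_ellipse.plane_normal)

    rng = np.random.default_rng(config.seed)
    population = []
    n = config.n_nodes
    for _ in range(config.n_subjects):
        z = rng.standard_normal(4)
        coords = base + (z * np.asarray(config.mode_sds)) @ modes
        coords = coords + config.noise_sd * rng.standard_normal(coords.shape)
        population.append(
            (
                AttachmentNodeSet(nodes=coords[: 3 * n].reshape(-1, 3), side="acetabular"),
                AttachmentNodeSet(nodes=coords[3 * n :].reshape(-1, 3), side="femoral"),
            )
        )
    return population


@dataclass
class SyntheticSpecimen:
    """A simulated "cadaveric" hip with known ground truth.

    ``laxity_measured`` holds only the experimental I-E subset (16 values)
    with additive N(0, noise_sd²) measurement noise; the full noise-free
    profile is reproducible from ``true_params`` via the simulator.
    """

    true_params: CapsuleParameters
    true_scores: np.ndarray
    acetabular: AttachmentNodeSet
    femoral: AttachmentNodeSet
    laxity_measured: dict
    noise_sd_deg: float
    seed: int

    def save(self, truth_path, laxity_path) -> None:
        """Truth JSON + measured-laxity CSV, separable for blinded recovery tests."""
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "stiffness": self.true_params.stiffness.tolist(),
                    "pre_strain": self.true_params.pre_strain.tolist(),
                    "scores": self.true_scores.tolist(),
                    "noise_sd_deg": self.noise_sd_deg,
                    "seed": self.seed,
                },
                fh,
            )
        rows = []
        for name, value in self.laxity_measured.items():
            direction, flexion, torque = name.rsplit("_", 2)
            rows.append((direction, int(flexion), float(torque[:-2]), value))
        pd.DataFrame(
            rows, columns=["direction", "flexion_deg", "torque_Nm", "rotation_deg"]
        ).to_csv(laxity_path, index=False)


def synthetic_specimen(
    shape_model: ShapeModel,
    dists: ParameterDistributions | None = None,
    noise_sd_deg: float = 1.0,
    seed: int = 0,
    mesh_config: MeshConfig | None = None,
) -> SyntheticSpecimen:
    """Draw one synthetic specimen and measure its experimental laxity subset."""
    if noise_sd_deg < 0:
        raise ValueError("noise_sd_deg must be non-negative")
    dists = dists or ParameterDistributions.default()
    mesh_config = mesh_config or MeshConfig()
    rng = np.random.default_rng(seed)
    # plain truncated-normal draws (a single specimen, not a stratified design)
    u = rng.uniform(stats.norm.cdf(-dists.trunc_z), stats.norm.cdf(dists.trunc_z))
    values = dists.mean + dists.sd * stats.norm.ppf(u)
    params = CapsuleParameters(stiffness=values[:6], pre_strain=values[6:12])
    scores = values[12:16]

    ace, fem = reconstruct_attachments(shape_model, scores)
    mesh = build_capsule_mesh(ace, fem, mesh_config.sphere, mesh_config.n_lines)
    profile = evaluate_laxity_profile(mesh, params, frame=mesh_config.frame)
    full = profile.as_dict()
    measured = {
        name: full[name] + noise_sd_deg * rng.standard_normal() for name in EXPERIMENT_METRICS
    }
    return SyntheticSpecimen(
        true_params=params,
        true_scores=scores,
        acetabular=ace,
        femoral=fem,
        laxity_measured=measured,
        noise_sd_deg=noise_sd_deg,
        seed=seed,
    )
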