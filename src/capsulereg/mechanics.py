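"""Reduced-order quasi-static capsule mechanics.

Each longitudinal capsule line is a nonlinear tension-only spring following
the wrapped (tangent–arc–tangent) path around the femoral-head sphere.  The
femur rotates rigidly about the hip center through an intrinsic
flexion → ab/adduction → internal/external-rotation sequence.  Laxity is the
rotation at which the capsule's restoring torque about the loaded axis
balances the applied torque (1 or 5 Nm), reproducing a quasi-static torque
ramp from the neutral rotation: the joint first settles at its passive
equilibrium, then follows the stable branch of the torque–rotation curve,
with each crossing refined by bisection.

Conventions (right hip, anatomic frame with anterior/superior/lateral
positive): flexion rotates about +M-L, internal rotation about +S-I,
external about -S-I, adduction about +A-P, abduction about -A-P.  The femur
points inferiorly (-S-I) at neutral.

Pre-strain controls tautness through the slack length
``L0 = reference_length * pre_strain**(-SLACK_EXPONENT)``: pre-strain of one
means the line is exactly taut at the neutral (as-meshed) pose, and smaller
values carry progressively more slack.  A raw stretch-ratio reading
(``L0 = reference_length / pre_strain``) would hand the deeply sub-unity
sectors more slack than sphere wrapping can ever take up, leaving them
permanently unrecruited; the attenuated exponent (first-order proportional to
the stretch-ratio form near pre-strain one) keeps all six sectors recruitable
within physiologic rotations, matching the expected capsule recruitment
pattern where every sector engages during I-E or Ad-Ab rotation at 0–90°
flexion.  The spring law has a quadratic toe up to an elongation of twice the
toe elongation (default toe strain 3% of slack length) and is linear beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import AnatomicFrame, CapsuleMesh
from .wrapping import wrap_geometry, wrapped_length  # noqa: F401  (re-export)

__all__ = [
    "CapsuleParameters",
    "HipPose",
    "LaxityProfile",
    "LaxityConvergenceError",
    "spring_force",
    "spring_energy",
    "wrapped_length",
    "restoring_torque",
    "solve_laxity",
    "evaluate_laxity_profile",
    "DIRECTIONS",
    "STANDARD_FLEXIONS",
    "TORQUE_LEVELS",
]

DIRECTIONS = ("internal", "external", "abduction", "adduction")
STANDARD_FLEXIONS = (0, 30, 45, 60, 90)
TORQUE_LEVELS = (1.0, 5.0)

#: toe-region elongation as a fraction of slack length (typical ligament toe strain)
TOE_STRAIN = 0.03

#: slack-attenuation exponent in L0 = reference_length * pre_strain**(-SLACK_EXPONENT)
SLACK_EXPONENT = 0.2


class LaxityConvergenceError(RuntimeError):
    """Raised when the target torque is unreachable within the rotation limits."""


@dataclass(frozen=True)
class CapsuleParameters:
    """Per-sector capsule mechanics: 6 stiffnesses (N/mm) and 6 pre-strains."""

    stiffness: np.ndarray
    pre_strain: np.ndarray

    def __post_init__(self) -> None:
        stiffness = np.asarray(self.stiffness, dtype=float)
        pre_strain = np.asarray(self.pre_strain, dtype=float)
        object.__setattr__(self, "stiffness", stiffness)
        object.__setattr__(self, "pre_strain", pre_strain)
        if stiffness.shape != (6,) or pre_strain.shape != (6,):
            raise ValueError("stiffness and pre_strain must each have 6 sector values")
        if np.any(stiffness <= 0):
            raise ValueError("sector stiffness must be positive")
        if np.any(pre_strain <= 0) or np.any(pre_strain > 1.5):
            raise ValueError("pre_strain must lie in (0, 1.5]")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.stiffness, self.pre_strain])


@dataclass(frozen=True)
class HipPose:
    """Hip orientation in degrees (intrinsic flexion -> ab/ad -> I-E)."""

    flexion: float = 0.0
    abduction: float = 0.0
    internal_rotation: float = 0.0


def spring_force(
    elongation: np.ndarray, line_stiffness: float, toe_elongation: float
) -> np.ndarray:
    """Tension-only nonlinear spring law (N).

    Zero in compression; quadratic toe ``k d^2 / (4 dt)`` for elongations up
    to ``2 dt``; linear ``k (d - dt)`` beyond.  Force and slope are both
    continuous at the toe-to-linear transition.
    """
    k = np.asarray(line_stiffness, dtype=float)
    dt = np.asarray(toe_elongation, dtype=float)
    if np.any(k <= 0) or np.any(dt <= 0):
        raise ValueError("line stiffness and toe elongation must be positive")
    d = np.asarray(elongation, dtype=float)
    toe = k * d**2 / (4.0 * dt)
    lin = k * (d - dt)
    return np.where(d <= 0, 0.0, np.where(d <= 2.0 * dt, toe, lin))


def spring_energy(
    elongation: np.ndarray, line_stiffness: float, toe_elongation: float
) -> np.ndarray:
    """Strain energy (N·mm) stored in the spring law of :func:`spring_force`."""
    k = np.asarray(line_stiffness, dtype=float)
    dt = np.asarray(toe_elongation, dtype=float)
    d = np.asarray(elongation, dtype=float)
    toe = k * d**3 / (12.0 * dt)
    e_toe_end = 2.0 * k * dt**2 / 3.0
    lin = e_toe_end + 0.5 * k * ((d - dt) ** 2 - dt**2)
    return np.where(d <= 0, 0.0, np.where(d <= 2.0 * dt, toe, lin))


@dataclass(frozen=True)
class LaxityProfile:
    """The 40 laxity metrics: rotation (deg) per direction x flexion x torque."""

    rotations: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotations, dtype=float)
        object.__setattr__(self, "rotations", rot)
        if rot.shape != (len(self.metric_names()),):
            raise ValueError(f"expected {len(self.metric_names())} laxity values")

    @staticmethod
    def metric_names(
        directions: Iterable[str] = DIRECTIONS,
        flexions: Iterable[int] = STANDARD_FLEXIONS,
        torques: Iterable[float] = TORQUE_LEVELS,
    ) -> list[str]:
        return [
            f"{d}_{f}_{t:g}Nm" for d in directions for f in flexions for t in torques
        ]

    def get(self, direction: str, flexion: int, torque: float) -> float:
        key = f"{direction}_{flexion}_{torque:g}Nm"
        return float(self.rotations[self.metric_names().index(key)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.metric_names(), map(float, self.rotations)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        i = 0
        for d in DIRECTIONS:
            for f in STANDARD_FLEXIONS:
                for t in TORQUE_LEVELS:
                    rows.append((d, f, t, float(self.rotations[i])))
                    i += 1
        return pd.DataFrame(
            rows, columns=["direction", "flexion_deg", "torque_Nm", "rotation_deg"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LaxityProfile":
        df = pd.read_csv(path)
        lookup = {
            (r.direction, int(r.flexion_deg), float(r.torque_Nm)): float(r.rotation_deg)
            for r in df.itertuples()
        }
        values = [
            lookup[(d, f, t)]
            for d in DIRECTIONS
            for f in STANDARD_FLEXIONS
            for t in TORQUE_LEVELS
        ]
        return cls(rotations=np.array(values))


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary unit axis (Rodrigues)."""
    theta = np.deg2rad(angle_deg)
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


_DIRECTION_AXIS_SIGN = {
    "internal": ("si", 1.0),
    "external": ("si", -1.0),
    "adduction": ("ap", 1.0),
    "abduction": ("ap", -1.0),
}


def direction_axis(direction: str, frame: AnatomicFrame) -> np.ndarray:
    """Signed rotation axis for a laxity test direction at zero flexion."""
    try:
        name, sign = _DIRECTION_AXIS_SIGN[direction]
    except KeyError:
        raise ValueError(f"unknown laxity direction {direction!r}") from None
    return sign * getattr(frame, name)


def pose_rotation(pose: HipPose, frame: AnatomicFrame) -> np.ndarray:
    """Rotation matrix for an intrinsic flexion -> ab/ad -> I-E sequence."""
    r_flex = _axis_rotation(frame.ml, pose.flexion)
    r_abad = _axis_rotation(frame.ap, pose.abduction)
    r_ie = _axis_rotation(frame.si, pose.internal_rotation)
    return r_flex @ r_abad @ r_ie


@dataclass
class _LineMechanics:
    """Precomputed per-line spring constants for one (mesh, parameters) pair."""

    k_line: np.ndarray
    slack_length: np.ndarray
    toe_elongation: np.ndarray
    insertion_local: np.ndarray  # insertion nodes relative to hip center


def _prepare_lines(mesh: CapsuleMesh, params: CapsuleParameters) -> _LineMechanics:
    sector_idx = mesh.line_sector - 1
    lines_per_sector = np.bincount(sector_idx, minlength=6).astype(float)
    k_line = params.stiffness[sector_idx] / lines_per_sector[sector_idx]
    slack = mesh.reference_length * params.pre_strain[sector_idx] ** (-SLACK_EXPONENT)
    toe = TOE_STRAIN * slack
    return _LineMechanics(
        k_line=k_line,
        slack_length=slack,
        toe_elongation=toe,
        insertion_local=mesh.insertion_nodes - mesh.hip_center,
    )


def _torque_at(mesh: CapsuleMesh, pre: _LineMechanics, rot: np.ndarray, axis: np.ndarray) -> float:
    """Capsule restoring torque (Nm) resisting rotation about ``axis``."""
    p1 = pre.insertion_local @ rot.T + mesh.hip_center
    lengths, tangents, _ = wrap_geometry(mesh.origin_nodes, p1, mesh.head_sphere)
    elong = lengths - pre.slack_length
    f = spring_force(elong, pre.k_line, pre.toe_elongation)
    forces = f[:, None] * tangents
    torque_nmm = np.einsum("ij,j->", np.cross(p1 - mesh.hip_center, forces), axis)
    return -torque_nmm / 1000.0


def restoring_torque(
    mesh: CapsuleMesh,
    params: CapsuleParameters,
    pose: HipPose,
    axis: np.ndarray,
    frame: AnatomicFrame | None = None,
) -> float:
    """Capsule torque (Nm) resisting rotation about the given global-frame axis.

    Positive values resist positive rotation about ``axis``.  The femoral
    insertion nodes are rigidly rotated about the hip center by the pose;
    per-line tension acts along the wrapped path's departure tangent at the
    insertion.
    """
    frame = frame or AnatomicFrame()
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("axis must be a unit vector")
    pre = _prepare_lines(mesh, params)
    return _torque_at(mesh, pre, pose_rotation(pose, frame), axis)


_MAX_ROTATION = 175.0

_MARCH_STEP = 5.0


def _bisect_up_crossing(torque_fn, target: float, lo: float, hi: float, xtol: float) -> float:
    """Bisect an up-crossing of ``target`` bracketed by [lo, hi]."""
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if torque_fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _settle(torque_fn, xtol: float) -> float:
    """Passive equilibrium reached from the neutral rotation.

    The restoring torque is the gradient of the capsule strain energy, so the
    joint slides downhill from zero rotation to the nearest stable zero
    (an up-crossing of zero resistance).
    """
    g0 = torque_fn(0.0)
    if g0 == 0.0:
        return 0.0
    if g0 < 0:
        lo, g_lo = 0.0, g0
        hi = _MARCH_STEP
        g_hi = torque_fn(hi)
        while g_hi < 0:
            if hi >= _MAX_ROTATION:
                raise LaxityConvergenceError("no passive equilibrium within rotation limits")
            lo, g_lo = hi, g_hi
            hi = min(hi + _MARCH_STEP, _MAX_ROTATION)
            g_hi = torque_fn(hi)
        return _bisect_up_crossing(torque_fn, 0.0, lo, hi, xtol)
    hi, g_hi = 0.0, g0
    lo = -_MARCH_STEP
    g_lo = torque_fn(lo)
    while g_lo > 0:
        if lo <= -_MAX_ROTATION:
            raise LaxityConvergenceError("no passive equilibrium within rotation limits")
        hi, g_hi = lo, g_lo
        lo = max(lo - _MARCH_STEP, -_MAX_ROTATION)
        g_lo = torque_fn(lo)
    return _bisect_up_crossing(torque_fn, 0.0, lo, hi, xtol)


def _ramp_to(torque_fn, target: float, start: float, xtol: float) -> float:
    """Quasi-static torque ramp: first up-crossing of ``target`` at or beyond ``start``.

    Mirrors the experiment's ramp-shaped torque waveform: the joint follows
    the stable branch in the loaded direction, jumping past any local torque
    dips (snap-through) rather than selecting spurious unstable roots.
    """
    lo = start
    g_lo = torque_fn(lo)
    if g_lo >= target:
        return lo
    hi = lo + _MARCH_STEP
    g_hi = torque_fn(hi)
    while g_hi < target:
        if hi >= _MAX_ROTATION:
            raise LaxityConvergenceError(
                f"target torque {target:g} Nm unreachable within ±{_MAX_ROTATION}°"
            )
        lo, g_lo = hi, g_hi
        hi = min(hi + _MARCH_STEP, _MAX_ROTATION)
        g_hi = torque_fn(hi)
    return _bisect_up_crossing(torque_fn, target, lo, hi, xtol)


def solve_laxity(
    mesh: CapsuleMesh,
    params: CapsuleParameters,
    flexion: float,
    direction: str,
    torque_target: float,
    frame: AnatomicFrame | None = None,
    xtol: float = 1e-3,
) -> float:
    """Rotation (deg) at which the capsule resists ``torque_target`` Nm.

    Follows a quasi-static torque ramp from the neutral rotation: settle at
    the passive equilibrium, then march along the loaded direction to the
    first up-crossing of the target torque (bisected to ``xtol``).  The
    non-loaded rotation DOF is held neutral; rotation is positive in the
    loaded direction.  Raises :class:`LaxityConvergenceError` if the target
    torque is unreachable within ±175°.
    """
    if torque_target <= 0:
        raise ValueError("torque_target must be positive")
    frame = frame or AnatomicFrame()
    pre = _prepare_lines(mesh, params)
    axis0 = direction_axis(direction, frame)
    r_flex = _axis_rotation(frame.ml, flexion)
    axis_loaded = r_flex @ axis0

    def torque_fn(theta: float) -> float:
        rot = r_flex @ _axis_rotation(axis0, theta)
        return _torque_at(mesh, pre, rot, axis_loaded)

    return _ramp_to(torque_fn, torque_target, _settle(torque_fn, xtol), xtol)


def evaluate_laxity_profile(
    mesh: CapsuleMesh,
    params: CapsuleParameters,
    frame: AnatomicFrame | None = None,
    xtol: float = 1e-3,
) -> LaxityProfile:
    """Solve all 20 (direction, flexion) cases, reading off 1 and 5 Nm rotations.

    Failures are re-raised with the (direction, flexion) case attached.
    """
    frame = frame or AnatomicFrame()
    pre = _prepare_lines(mesh, params)
    values = np.empty(40)
    i = 0
    for direction in DIRECTIONS:
        axis0 = direction_axis(direction, frame)
        for flexion in STANDARD_FLEXIONS:
            r_flex = _axis_rotation(frame.ml, flexion)
            axis_loaded = r_flex @ axis0

            def torque_fn(theta: float) -> float:
                rot = r_flex @ _axis_rotation(axis0, theta)
                return _torque_at(mesh, pre, rot, axis_loaded)

            try:
                theta0 = _settle(torque_fn, xtol)
                theta1 = _ramp_to(torque_fn, TORQUE_LEVELS[0], theta0, xtol)
                # the ramp continues from the 1 Nm rotation toward 5 Nm
                theta5 = _ramp_to(torque_fn, TORQUE_LEVELS[1], theta1, xtol)
            except LaxityConvergenceError as err:
                raise LaxityConvergenceError(
                    f"{err} [direction={direction}, flexion={flexion}°]"
                ) from err
            values[i] = theta1
            values[i + 1] = theta5
            i += 2
    return LaxityProfile(rotations=values)
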