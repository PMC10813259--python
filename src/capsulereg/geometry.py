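"""Attachment-site geometry and the parametric six-sector capsule mesh.

The hip capsule is idealized as a cylindrical sleeve running from an ellipse
fit around the acetabular rim to an ellipse fit around the femoral
intertrochanteric crest.  Both ellipses are resampled into a fixed number of
arc-length-equispaced, index-corresponded nodes starting at the most superior
point, and corresponding nodes are joined by longitudinal spring lines grouped
into six circumferential sectors (approximating the named capsular ligaments,
numbered from the most superior line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import EllipseModel

from .wrapping import Sphere, wrap_geometry

__all__ = [
    "AnatomicFrame",
    "EllipseSpec",
    "AttachmentNodeSet",
    "CapsuleMesh",
    "fit_ellipse_3d",
    "resample_ellipse",
    "intertrochanteric_plane",
    "build_capsule_mesh",
]


class DegenerateGeometryError(ValueError):
    """Raised for geometrically degenerate landmark configurations."""


@dataclass(frozen=True)
class AnatomicFrame:
    """Right-handed anatomic coordinate frame.

    ``axes`` rows are the anterior–posterior (A-P, anterior positive),
    superior–inferior (S-I, superior positive) and medial–lateral (M-L,
    lateral positive) unit directions.  Origin at the joint center (mm).
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of row unit vectors")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("anatomic axes must be orthonormal")
        if not np.allclose(np.cross(self.axes[0], self.axes[1]), self.axes[2], atol=1e-9):
            raise ValueError("anatomic frame must be right-handed (AP x SI = ML)")

    @property
    def ap(self) -> np.ndarray:
        return self.axes[0]

    @property
    def si(self) -> np.ndarray:
        return self.axes[1]

    @property
    def ml(self) -> np.ndarray:
        return self.axes[2]


@dataclass(frozen=True)
class EllipseSpec:
    """A planar ellipse in 3D, all lengths in mm."""

    center: np.ndarray
    plane_normal: np.ndarray
    major_axis_dir: np.ndarray
    semi_major: float
    semi_minor: float

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        normal = np.asarray(self.plane_normal, dtype=float)
        major = np.asarray(self.major_axis_dir, dtype=float)
        normal = normal / np.linalg.norm(normal)
        major = major / np.linalg.norm(major)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "plane_normal", normal)
        object.__setattr__(self, "major_axis_dir", major)
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if abs(float(normal @ major)) > 1e-9:
            raise ValueError("major_axis_dir must lie in the ellipse plane")

    @property
    def minor_axis_dir(self) -> np.ndarray:
        return np.cross(self.plane_normal, self.major_axis_dir)

    def points_at(self, t: np.ndarray) -> np.ndarray:
        """Ellipse points at parameter angles ``t`` (not arc length)."""
        t = np.asarray(t, dtype=float)
        return (
            self.center
            + self.semi_major * np.cos(t)[:, None] * self.major_axis_dir
            + self.semi_minor * np.sin(t)[:, None] * self.minor_axis_dir
        )


@dataclass
class AttachmentNodeSet:
    """Closed loop of corresponded attachment nodes (mm).

    Node 0 is placed at the most superior point of the loop when produced by
    :func:`resample_ellipse`; synthetic perturbation can move individual nodes
    slightly, so the start convention is enforced at resampling, not here.
    """

    nodes: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be an (n, 3) array")
        if self.side not in ("acetabular", "femoral"):
            raise ValueError("side must be 'acetabular' or 'femoral'")

    def __len__(self) -> int:
        return self.nodes.shape[0]


@dataclass
class CapsuleMesh:
    """Reduced capsule representation: one path-spring per longitudinal line.

    ``reference_length`` is the as-meshed wrapped path length of each line at
    the neutral pose; slack lengths are derived from it via sector pre-strain.
    Sector ids run 1..6, in contiguous circumferential blocks numbered from
    the most superior line.
    """

    origin_nodes: np.ndarray
    insertion_nodes: np.ndarray
    line_sector: np.ndarray
    reference_length: np.ndarray
    head_sphere: Sphere

    def __post_init__(self) -> None:
        self.origin_nodes = np.asarray(self.origin_nodes, dtype=float)
        self.insertion_nodes = np.asarray(self.insertion_nodes, dtype=float)
        self.line_sector = np.asarray(self.line_sector, dtype=int)
        self.reference_length = np.asarray(self.reference_length, dtype=float)

    @property
    def n_lines(self) -> int:
        return self.origin_nodes.shape[0]

    @property
    def hip_center(self) -> np.ndarray:
        return self.head_sphere.center


def fit_ellipse_3d(points: np.ndarray) -> EllipseSpec:
    """Best-fit ellipse to >=6 roughly coplanar 3D points.

    The plane is the least-squares plane (smallest-variance direction of the
    centered points); the projected points are then fit with a direct
    least-squares conic constrained to an ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise ValueError("fit_ellipse_3d requires at least 6 three-dimensional points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("points are (near-)collinear; ellipse fit is rank-deficient")
    e0, e1, normal = vt[0], vt[1], vt[2]

    xy = np.column_stack([centered @ e0, centered @ e1])
    try:
        model = EllipseModel.from_estimate(xy)
        if not model:
            raise ValueError("direct conic fit failed for the supplied points")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:  # older scikit-image: estimate() + flat params tuple
        model = EllipseModel()
        if not model.estimate(xy):
            raise ValueError("direct conic fit failed for the supplied points")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise ValueError("direct conic fit failed for the supplied points")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0

    center = centroid + xc * e0 + yc * e1
    major = np.cos(theta) * e0 + np.sin(theta) * e1
    return EllipseSpec(
        center=center,
        plane_normal=normal,
        major_axis_dir=major,
        semi_major=float(a),
        semi_minor=float(b),
    )


def _traversal_sign(ellipse: EllipseSpec, frame: AnatomicFrame) -> float:
    """+1 keeps the parameterization direction, -1 reverses it.

    Traversal is counter-clockwise when viewed from the lateral side; the
    native ``points_at`` direction is counter-clockwise about ``plane_normal``,
    so reverse when the normal points medially.  Ties fall back to the A-P and
    then S-I components.
    """
    for axis in (frame.ml, frame.ap, frame.si):
        comp = float(ellipse.plane_normal @ axis)
        if abs(comp) > 1e-9:
            return 1.0 if comp > 0 else -1.0
    return 1.0


def resample_ellipse(
    ellipse: EllipseSpec,
    n: int,
    frame: AnatomicFrame,
    side: str = "acetabular",
    _dense: int = 40_000,
) -> AttachmentNodeSet:
    """Resample an ellipse into ``n`` arc-length-equispaced nodes.

    Node 0 sits at the most superior point of the loop (maximal S-I
    coordinate); ties are broken toward the smaller parameter after sorting
    by (S-I, A-P).  Arc length is parameterized by trapezoidal quadrature of
    the analytic speed and inverted by interpolation.
    """
    if n < 8:
        raise ValueError("resample_ellipse requires n >= 8")
    a, b = ellipse.semi_major, ellipse.semi_minor
    u, v = ellipse.major_axis_dir, ellipse.minor_axis_dir

    u_s = float(u @ frame.si)
    v_s = float(v @ frame.si)
    # maximize superior coordinate c_s + a*u_s*cos t + b*v_s*sin t
    if abs(a * u_s) < 1e-12 and abs(b * v_s) < 1e-12:
        # loop lies in a transverse plane: every node equally superior; pick t=0
        # then break the tie by the anterior (A-P) component
        u_a, v_a = float(u @ frame.ap), float(v @ frame.ap)
        t0 = 0.0 if abs(a * u_a) < 1e-12 and abs(b * v_a) < 1e-12 else np.arctan2(b * v_a, a * u_a)
    else:
        t0 = np.arctan2(b * v_s, a * u_s)

    sign = _traversal_sign(ellipse, frame)
    phi = np.linspace(0.0, 2.0 * np.pi, _dense + 1)
    t = t0 + sign * phi
    speed = np.hypot(a * np.sin(t), b * np.cos(t))  # |dp/dt|, u ⟂ v unit vectors
    arclen = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) * 0.5 * np.diff(phi))])
    perimeter = arclen[-1]
    targets = np.arange(n) * perimeter / n
    phi_nodes = np.interp(targets, arclen, phi)
    return AttachmentNodeSet(nodes=ellipse.points_at(t0 + sign * phi_nodes), side=side)


def intertrochanteric_plane(
    greater_troch: np.ndarray,
    lesser_troch: np.ndarray,
    frame: AnatomicFrame,
    femur_surface: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate the intertrochanteric-crest plane of the femoral insertion.

    The plane normal is the cross product of the greater-to-lesser trochanter
    vector with the A-P axis; the plane is then translated until it contains
    the most prominent point on the posterior aspect of the femur surface.
    Returns ``(point_on_plane, unit_normal)``.
    """
    gt = np.asarray(greater_troch, dtype=float)
    lt = np.asarray(lesser_troch, dtype=float)
    surface = np.asarray(femur_surface, dtype=float)
    if surface.ndim != 2 or surface.shape[1] != 3 or surface.shape[0] == 0:
        raise ValueError("femur_surface must be a non-empty (n, 3) point set")
    troch_vec = gt - lt
    if np.linalg.norm(troch_vec) < 1e-12:
        raise DegenerateGeometryError("greater and lesser trochanter points coincide")
    normal = np.cross(troch_vec, frame.ap)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-9 * np.linalg.norm(troch_vec):
        raise DegenerateGeometryError("trochanter vector is parallel to the A-P axis")
    normal = normal / nrm
    # most prominent posterior point = minimal anterior coordinate
    posterior_idx = int(np.argmin(surface @ frame.ap))
    return surface[posterior_idx].copy(), normal


def build_capsule_mesh(
    acetabular: AttachmentNodeSet,
    femoral: AttachmentNodeSet,
    head_sphere: Sphere,
    n_lines: int = 36,
) -> CapsuleMesh:
    """Connect corresponded attachment nodes into the six-sector spring mesh.

    ``n_lines`` longitudinal lines are subsampled uniformly from the node
    loops and partitioned into 6 equal contiguous circumferential sectors,
    numbered from the most superior line (line 0).  Reference lengths are the
    wrapped path lengths at the as-meshed neutral pose.
    """
    n_nodes = len(acetabular)
    if len(femoral) != n_nodes:
        raise ValueError("acetabular and femoral node sets must have equal length")
    if n_lines % 6 != 0:
        raise ValueError("n_lines must be divisible by 6")
    if n_nodes % n_lines != 0:
        raise ValueError("n_lines must divide the node count")

    step = n_nodes // n_lines
    idx = np.arange(0, n_nodes, step)
    origin = acetabular.nodes[idx]
    insertion = femoral.nodes[idx]
    sector = np.arange(n_lines) // (n_lines // 6) + 1
    lengths, _, _ = wrap_geometry(origin, insertion, head_sphere)
    return CapsuleMesh(
        origin_nodes=origin,
        insertion_nodes=insertion,
        line_sector=sector,
        reference_length=lengths,
        head_sphere=head_sphere,
    )
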