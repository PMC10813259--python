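"""Shortest-path geometry of a line spring wrapping a single sphere.

A capsule spring runs from a fixed origin point to an insertion point on the
femur.  When the straight segment between the endpoints would pass through the
femoral-head sphere, the spring instead follows the shortest path over the
sphere surface: a straight tangent segment, a great-circle arc, and a second
tangent segment.  Both the path length and the departure direction at the
insertion (needed for moment arms) are closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidGeometryError(ValueError):
    """Raised when a spring endpoint lies inside the wrapping sphere."""


@dataclass(frozen=True)
class Sphere:
    """Wrapping sphere (femoral head), coordinates in mm."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        if self.radius < 0:
            raise ValueError("sphere radius must be non-negative")


def wrap_geometry(
    p0: np.ndarray, p1: np.ndarray, sphere: Sphere
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Path lengths and departure tangents for line springs around a sphere.

    Parameters
    ----------
    p0, p1
        ``(n, 3)`` arrays of segment endpoints (mm).  ``p0`` is the fixed
        (acetabular) end, ``p1`` the moving (femoral) end.
    sphere
        Wrapping sphere.  A radius of zero disables wrapping entirely.

    Returns
    -------
    lengths : (n,) shortest-path lengths (mm).
    tangents : (n, 3) unit vectors at ``p1`` pointing from the insertion
        toward the path (the direction a tensioned spring pulls the femur).
    wrapped : (n,) boolean mask of lines in contact with the sphere.
    """
    P0 = np.atleast_2d(np.asarray(p0, dtype=float)) - sphere.center
    P1 = np.atleast_2d(np.asarray(p1, dtype=float)) - sphere.center
    r0 = np.linalg.norm(P0, axis=1)
    r1 = np.linalg.norm(P1, axis=1)
    R = sphere.radius

    if R > 0 and (np.any(r0 < R * (1 - 1e-9)) or np.any(r1 < R * (1 - 1e-9))):
        raise InvalidGeometryError("spring endpoint inside the wrapping sphere")

    seg = P1 - P0
    seg_len = np.linalg.norm(seg, axis=1)
    # closest approach of the straight segment to the sphere center
    denom = np.where(seg_len > 0, seg_len**2, 1.0)
    t = np.clip(-np.einsum("ij,ij->i", P0, seg) / denom, 0.0, 1.0)
    closest = P0 + t[:, None] * seg
    dmin = np.linalg.norm(closest, axis=1)

    wrapped = (R > 0) & (dmin < R * (1 - 1e-12)) & (seg_len > 0)

    lengths = seg_len.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tangents = np.where(
            seg_len[:, None] > 0, (P0 - P1) / np.where(seg_len == 0, 1.0, seg_len)[:, None], 0.0
        )

    if np.any(wrapped):
        w = wrapped
        a0, a1 = P0[w], P1[w]
        n0, n1 = r0[w], r1[w]
        cosg = np.clip(np.einsum("ij,ij->i", a0, a1) / (n0 * n1), -1.0, 1.0)
        gamma = np.arccos(cosg)
        beta0 = np.arccos(np.clip(R / n0, -1.0, 1.0))
        beta1 = np.arccos(np.clip(R / n1, -1.0, 1.0))
        arc = np.maximum(gamma - beta0 - beta1, 0.0)
        tan0 = np.sqrt(np.maximum(n0**2 - R**2, 0.0))
        tan1 = np.sqrt(np.maximum(n1**2 - R**2, 0.0))
        lengths[w] = tan0 + tan1 + R * arc

        # tangent point seen from p1, in the plane spanned by (p0, p1)
        e1 = a1 / n1[:, None]
        proj = np.einsum("ij,ij->i", a0, e1)
        perp = a0 - proj[:, None] * e1
        perp_norm = np.linalg.norm(perp, axis=1)
        # antipodal endpoints: wrap plane is degenerate, pick any perpendicular
        bad = perp_norm < 1e-12
        if np.any(bad):
            fallback = np.cross(e1[bad], np.array([1.0, 0.0, 0.0]))
            fn = np.linalg.norm(fallback, axis=1)
            redo = fn < 1e-12
            fallback[redo] = np.cross(e1[bad][redo], np.array([0.0, 1.0, 0.0]))
            perp[bad] = fallback
            perp_norm[bad] = np.linalg.norm(fallback, axis=1)
        e2 = perp / perp_norm[:, None]
        T1 = R * (np.cos(beta1)[:, None] * e1 + np.sin(beta1)[:, None] * e2)
        dep = T1 - a1
        tangents[w] = dep / np.linalg.norm(dep, axis=1)[:, None]

    return lengths, tangents, wrapped


def wrapped_length(p0: np.ndarray, p1: np.ndarray, sphere: Sphere) -> float:
    """Shortest path length (mm) between two points around a sphere.

    Euclidean distance when the straight segment clears the sphere; otherwise
    the tangent–arc–tangent path.  Raises :class:`InvalidGeometryError` if an
    endpoint lies inside the sphere.
    """
    lengths, _, _ = wrap_geometry(
        np.asarray(p0, dtype=float)[None, :], np.asarray(p1, dtype=float)[None, :], sphere
    )
    return float(lengths[0])
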