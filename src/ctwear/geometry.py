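"""Exact geometric primitives shared by surface extraction and sphere fitting.

All geometry is carried out in world millimetres, never in voxel indices:
clinical CT spacing is anisotropic, and every downstream quantity (radii,
centers, separations) is reported in mm.

The two workhorses are :func:`fit_plane` (the cup-rim plane defined by the
three rim landmarks) and :func:`circumspheres` (the unique sphere through
four non-coplanar points, evaluated in bulk for the random-sampling sphere
fitter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .errors import DegenerateGeometryError

#: A 3-vector of world coordinates in mm.
Point3 = npt.NDArray[np.float64]

# Degeneracy tolerances. Quadruples whose tetrahedron volume is below
# _COPLANAR_VOLUME_TOL give numerically unstable circumspheres and are
# rejected (the sampling caller simply discards them).
_COPLANAR_VOLUME_TOL = 1e-6  # mm^3
_COLINEAR_AREA_TOL = 1e-9  # mm^2


def as_point(p) -> Point3:
    """Coerce ``p`` to a finite float64 vector of shape (3,)."""
    arr = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite coordinates: {p!r}")
    return arr


@dataclass(frozen=True)
class Plane:
    """A plane through ``point`` with unit ``normal``."""

    point: Point3
    normal: Point3

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", as_point(self.point))
        n = as_point(self.normal)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("plane normal must have unit length")
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class SphereModel:
    """A sphere: center (mm) and radius (mm)."""

    center: Point3
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", as_point(self.center))
        r = float(self.radius)
        if not np.isfinite(r) or r <= 0:
            raise ValueError(f"sphere radius must be positive, got {r}")
        object.__setattr__(self, "radius", r)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def fit_plane(p1, p2, p3) -> Plane:
    """Plane through three noncolinear points.

    Raises
    ------
    DegenerateGeometryError
        If the points are coincident or colinear (triangle area below
        tolerance).
    """
    a, b, c = as_point(p1), as_point(p2), as_point(p3)
    cross = np.cross(b - a, c - a)
    area = 0.5 * float(np.linalg.norm(cross))
    if area <= _COLINEAR_AREA_TOL:
        raise DegenerateGeometryError(
            f"points are colinear or coincident (triangle area {area:.3g} mm^2)"
        )
    normal = cross / np.linalg.norm(cross)
    return Plane(point=a, normal=normal)


def point_plane_distance(p, plane: Plane) -> float:
    """Shortest (unsigned) distance in mm from ``p`` to ``plane``."""
    return abs(float(np.dot(as_point(p) - plane.point, plane.normal)))


def project_onto_plane(p, plane: Plane) -> Point3:
    """Orthogonal projection of ``p`` onto ``plane``."""
    p = as_point(p)
    return p - float(np.dot(p - plane.point, plane.normal)) * plane.normal


def circumspheres(quads: npt.ArrayLike):
    """Circumspheres of a batch of point quadruples.

    Solves, for each quadruple, the linear system expressing that the
    center is equidistant from all four points:
    ``2 (p_i - p_4) . c = |p_i|^2 - |p_4|^2`` for i = 1..3.

    Parameters
    ----------
    quads : array, shape (n, 4, 3)

    Returns
    -------
    centers : (n, 3) float array — NaN where degenerate
    radii : (n,) float array — NaN where degenerate
    ok : (n,) bool array — False where the quadruple is (near-)coplanar,
        i.e. its tetrahedron volume is below 1e-6 mm^3.
    """
    q = np.asarray(quads, dtype=float)
    if q.ndim != 3 or q.shape[1:] != (4, 3):
        raise ValueError(f"expected shape (n, 4, 3), got {q.shape}")
    n = q.shape[0]
    a = q[:, :3, :] - q[:, 3:4, :]  # rows p_i - p4
    vol = np.abs(np.linalg.det(a)) / 6.0
    ok = vol >= _COPLANAR_VOLUME_TOL
    centers = np.full((n, 3), np.nan)
    radii = np.full(n, np.nan)
    if np.any(ok):
        rhs = 0.5 * (
            np.sum(q[:, :3, :] ** 2, axis=2) - np.sum(q[:, 3:4, :] ** 2, axis=2)
        )
        c = np.linalg.solve(a[ok], rhs[ok][..., None])[..., 0]
        centers[ok] = c
        radii[ok] = np.linalg.norm(q[ok, 0, :] - c, axis=1)
    return centers, radii, ok


def circumsphere(p1, p2, p3, p4) -> SphereModel:
    """Unique sphere through four non-coplanar points.

    Raises
    ------
    DegenerateGeometryError
        If the four points are (near-)coplanar.
    """
    quad = np.stack([as_point(p) for p in (p1, p2, p3, p4)])[None]
    centers, radii, ok = circumspheres(quad)
    if not ok[0]:
        raise DegenerateGeometryError(
            "four points are coplanar; no unique circumsphere"
        )
    return SphereModel(center=centers[0], radius=float(radii[0]))
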