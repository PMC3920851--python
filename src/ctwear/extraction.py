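"""Landmark-constrained ray-cast surface extraction.

Seven operator landmarks bound the search for the two implant surfaces:

* three points on the cup rim (they define the rim plane),
* one point centered in the apical dome hole,
* one point shifted 5–10 mm outward from the apex along the cup axis,
* a spherical landmark around the head/stem junction,
* a spherical landmark enclosing the femoral head.

The extractor casts rays inward — from outside the cup toward its
estimated center over the apex-side hemisphere, and from the enclosing
sphere toward its center for the head — sampling the volume with trilinear
interpolation and recording the first position where the intensity exceeds
the metal threshold for a minimum number of consecutive samples, so that
isolated above-threshold voxels (noise) are ignored. Cup rays are capped at
a fraction (default 60%) of the starting radius so unused screw holes
cannot contribute deep spurious points; head rays that would pass through
the stem-junction sphere are discarded so the stem is never sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DegenerateGeometryError, EmptySurfaceError, LandmarkValidationError
from .geometry import (
    Plane,
    Point3,
    as_point,
    fit_plane,
    point_plane_distance,
    project_onto_plane,
)
from .volume import CTVolume

#: Head point count below which a warning is emitted (likely a too-small
#: enclosing sphere or a bad threshold).
_LOW_POINT_WARNING = 500

#: Ray start distance as a multiple of the starting radius.
_START_FACTOR = 1.2


@dataclass(frozen=True)
class SphereLandmark:
    """An operator landmark with an associated radius (a 3-D sphere)."""

    center: Point3
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", as_point(self.center))
        r = float(self.radius)
        if not np.isfinite(r) or r <= 0:
            raise LandmarkValidationError(
                f"spherical landmark radius must be positive, got {r}"
            )
        object.__setattr__(self, "radius", r)


@dataclass(frozen=True)
class LandmarkSet:
    """The seven operator landmarks, split into cup and head subsets."""

    cup_rim: np.ndarray  # (3, 3): three noncolinear points on the cup rim
    cup_apex: Point3  # centered in the apical dome hole
    cup_offset: Point3  # shifted 5-10 mm outward along the cup axis
    stem_junction: SphereLandmark
    head_enclosing: SphereLandmark

    def __post_init__(self) -> None:
        rim = np.asarray(self.cup_rim, dtype=float)
        if rim.shape != (3, 3):
            raise LandmarkValidationError(
                f"cup_rim must be three 3-D points, got shape {rim.shape}"
            )
        object.__setattr__(self, "cup_rim", rim)
        object.__setattr__(self, "cup_apex", as_point(self.cup_apex))
        object.__setattr__(self, "cup_offset", as_point(self.cup_offset))
        try:
            fit_plane(*rim)
        except DegenerateGeometryError as exc:
            raise LandmarkValidationError(f"cup rim points: {exc}") from exc

    def rim_plane(self) -> Plane:
        """The cup-rim plane, normal oriented toward the apex landmark."""
        plane = fit_plane(*self.cup_rim)
        if np.dot(self.cup_apex - plane.point, plane.normal) < 0:
            plane = Plane(point=plane.point, normal=-plane.normal)
        return plane


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the threshold-limited ray search.

    ``threshold`` is the metal intensity cutoff (same units as the volume);
    ``cup_range_fraction`` caps cup-ray travel at that fraction of the
    starting radius; ``min_run_length`` is the number of consecutive
    above-threshold samples required before a crossing counts;
    ``step_size`` defaults to half the smallest voxel spacing.
    """

    threshold: float
    cup_range_fraction: float = 0.60
    min_run_length: int = 3
    n_ray_directions: int = 4000
    step_size: float | None = None
    radius_landmark: str = "apex"  # or "offset"

    def __post_init__(self) -> None:
        if not (0 < self.cup_range_fraction <= 1):
            raise ValueError("cup_range_fraction must be in (0, 1]")
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")
        if self.n_ray_directions < 1:
            raise ValueError("n_ray_directions must be >= 1")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.radius_landmark not in ("apex", "offset"):
            raise ValueError("radius_landmark must be 'apex' or 'offset'")

    def effective_step(self, vol: CTVolume) -> float:
        return self.step_size if self.step_size is not None else float(
            np.min(vol.spacing) / 2.0
        )


@dataclass
class SurfacePointSet:
    """Candidate surface points with per-point bookkeeping for the fitter.

    ``offending_count`` is filled in by the pruning passes of the sphere
    fitter; ``valid`` marks points still considered inliers. ``ray_dirs``
    records the (unit) direction each point's ray was travelling, which
    makes the run-length rule re-checkable after the fact.
    """

    points: np.ndarray  # (n, 3) world mm
    offending_count: np.ndarray = None  # type: ignore[assignment]
    valid: np.ndarray = None  # type: ignore[assignment]
    ray_dirs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = len(self.points)
        if self.offending_count is None:
            self.offending_count = np.zeros(n, dtype=np.int64)
        else:
            self.offending_count = np.asarray(self.offending_count, dtype=np.int64)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.offending_count.shape != (n,) or self.valid.shape != (n,):
            raise ValueError("per-point arrays must match the number of points")
        if np.any(self.offending_count < 0):
            raise ValueError("offending counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def valid_points(self) -> np.ndarray:
        return self.points[self.valid]

    def copy(self) -> "SurfacePointSet":
        return SurfacePointSet(
            points=self.points.copy(),
            offending_count=self.offending_count.copy(),
            valid=self.valid.copy(),
            ray_dirs=None if self.ray_dirs is None else self.ray_dirs.copy(),
        )


def starting_radius(cup_rim_plane: Plane, apex) -> float:
    """Distance from the rim plane to the apical point: the search radius.

    Raises
    ------
    DegenerateGeometryError
        If the apex lies (numerically) on the rim plane.
    """
    d = point_plane_distance(apex, cup_rim_plane)
    if d < 1e-6:
        raise DegenerateGeometryError("apex landmark lies on the rim plane")
    return d


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit directions on the sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _orthonormal_basis(axis: np.ndarray) -> np.ndarray:
    """A rotation matrix whose third column is ``axis``."""
    w = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, w)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def fibonacci_hemisphere(n: int, axis) -> np.ndarray:
    """``n`` near-uniform unit directions on the hemisphere around ``axis``."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (i + 0.5) / n  # (0, 1]: strictly on the axis side
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    local = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return local @ _orthonormal_basis(as_point(axis)).T


def sample_intensity(vol: CTVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the volume at world points (..., 3).

    Positions outside the grid evaluate to the volume minimum, i.e. safely
    below any sensible metal threshold.
    """
    pts = np.asarray(points, dtype=float)
    idx = vol.world_to_index(pts)
    flat = idx.reshape(-1, 3).T
    vals = map_coordinates(
        vol.intensities,
        flat,
        order=1,
        mode="constant",
        cval=float(vol.intensities.min()),
    )
    return vals.reshape(pts.shape[:-1])


def _first_run_crossing(
    vol: CTVolume,
    starts: np.ndarray,
    dirs: np.ndarray,
    max_travel: float,
    step: float,
    threshold: float,
    min_run: int,
):
    """March each ray and find the first ``min_run``-long above-threshold run.

    Returns (points, hit_mask): the first sample of each qualifying run (no
    sub-voxel edge refinement) and which rays produced one. Rays that start
    inside metal (first sample already above threshold) have no outside-in
    crossing and are invalid.
    """
    n_steps = int(np.floor(max_travel / step)) + 1
    t = np.arange(n_steps) * step
    pts = starts[:, None, :] + t[None, :, None] * dirs[:, None, :]
    vals = sample_intensity(vol, pts)
    above = vals > threshold
    run = above[:, : above.shape[1] - (min_run - 1)].copy()
    for s in range(1, min_run):
        run &= above[:, s : above.shape[1] - (min_run - 1) + s]
    hit = run.any(axis=1)
    first = run.argmax(axis=1)
    hit &= ~above[:, 0]  # must search from outside the metal
    points = starts + t[first][:, None] * dirs
    return points, hit


def extract_cup_surface(
    vol: CTVolume, lm: LandmarkSet, cfg: ExtractionConfig
) -> SurfacePointSet:
    """Candidate points on the outer hemisphere of the acetabular cup.

    Rays are cast inward toward the estimated cup center (the apex
    projected onto the rim plane) from outside the starting radius, over
    the apex-side hemisphere; ray travel is capped at
    ``cup_range_fraction`` of the starting radius so rays passing through
    unused screw holes stop before reaching interior structures.

    Raises
    ------
    EmptySurfaceError
        If no ray finds a qualifying threshold crossing.
    """
    plane = lm.rim_plane()
    radius_pt = lm.cup_apex if cfg.radius_landmark == "apex" else lm.cup_offset
    r0 = starting_radius(plane, radius_pt)
    center_est = project_onto_plane(lm.cup_apex, plane)
    out_dirs = fibonacci_hemisphere(cfg.n_ray_directions, plane.normal)
    starts = center_est[None, :] + _START_FACTOR * r0 * out_dirs
    ray_dirs = -out_dirs
    step = cfg.effective_step(vol)
    points, hit = _first_run_crossing(
        vol,
        starts,
        ray_dirs,
        max_travel=cfg.cup_range_fraction * r0,
        step=step,
        threshold=cfg.threshold,
        min_run=cfg.min_run_length,
    )
    hit &= vol.contains(points)
    if not np.any(hit):
        raise EmptySurfaceError(
            "no cup surface points found; check the intensity threshold "
            "and the cup landmarks"
        )
    return SurfacePointSet(points=points[hit], ray_dirs=ray_dirs[hit])


def extract_head_surface(
    vol: CTVolume, lm: LandmarkSet, cfg: ExtractionConfig
) -> SurfacePointSet:
    """Candidate points on the femoral head sphere.

    Rays start on the head-enclosing landmark sphere and march toward its
    center; the first qualifying threshold crossing is the entry into
    metal (heads are not necessarily solid, so only the outer crossing is
    trusted). Any ray whose path would intersect the stem-junction
    landmark sphere is discarded, which keeps the stem out of the point
    set.
    """
    enc = lm.head_enclosing
    out_dirs = fibonacci_sphere(cfg.n_ray_directions)
    starts = enc.center[None, :] + enc.radius * out_dirs
    ray_dirs = -out_dirs

    # Discard rays whose segment (start -> enclosing center) passes through
    # the stem-junction sphere.
    w = lm.stem_junction.center[None, :] - starts
    t_closest = np.clip(np.einsum("ij,ij->i", w, ray_dirs), 0.0, enc.radius)
    closest = starts + t_closest[:, None] * ray_dirs
    miss_stem = (
        np.linalg.norm(closest - lm.stem_junction.center[None, :], axis=1)
        >= lm.stem_junction.radius
    )
    starts, ray_dirs = starts[miss_stem], ray_dirs[miss_stem]
    if len(starts) == 0:
        raise EmptySurfaceError(
            "all head rays intersect the stem-junction sphere; check landmarks"
        )

    step = cfg.effective_step(vol)
    points, hit = _first_run_crossing(
        vol,
        starts,
        ray_dirs,
        max_travel=enc.radius,
        step=step,
        threshold=cfg.threshold,
        min_run=cfg.min_run_length,
    )
    hit &= vol.contains(points)
    if not np.any(hit):
        raise EmptySurfaceError(
            "no head surface points found; check the intensity threshold "
            "and the head-enclosing landmark"
        )
    n_hit = int(np.count_nonzero(hit))
    if n_hit < _LOW_POINT_WARNING:
        warnings.warn(
            f"only {n_hit} head surface points found; the enclosing landmark "
            "may be too small or the threshold too high",
            RuntimeWarning,
            stacklevel=2,
        )
    return SurfacePointSet(points=points[hit], ray_dirs=ray_dirs[hit])


def perturb_landmarks(
    lm: LandmarkSet, amplitude_mm: float, rng: np.random.Generator
) -> LandmarkSet:
    """Jitter every landmark position uniformly by up to ±``amplitude_mm``
    per coordinate — a cheap emulation of operator placement variability."""

    def jit(p: np.ndarray) -> np.ndarray:
        return p + rng.uniform(-amplitude_mm, amplitude_mm, size=p.shape)

    return LandmarkSet(
        cup_rim=jit(lm.cup_rim),
        cup_apex=jit(lm.cup_apex),
        cup_offset=jit(lm.cup_offset),
        stem_junction=replace(lm.stem_junction, center=jit(lm.stem_junction.center)),
        head_enclosing=replace(
            lm.head_enclosing, center=jit(lm.head_enclosing.center)
        ),
    )
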