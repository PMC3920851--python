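"""Robust sphere fitting to extracted surface points.

The estimator is a random-sampling consensus scheme specialized to
spheres. Repeatedly drawing four surface points (every pair at least
2 mm apart, to avoid near-degenerate circumspheres) yields one candidate
center/radius per draw. The procedure is:

1. *Initialization* — histogram the circumsphere radii of 80,000 random
   quadruples (1000 bins over 0–100 mm); the maximal bin gives the initial
   radius, and the component-wise median of the in-bin centers gives the
   initial center.
2. *Coarse prune* — re-sample quadruples and count, per point, how often
   it participated in a circumsphere whose radius missed the initial
   radius by more than ±2 mm; high-count points are removed.
3. *Fine prune* — same again at ±(twice the slice thickness), 0.4 mm at
   0.2 mm slices.
4. *Final estimate* — geometric least squares over the surviving points.

The offending-count cutoff can be absolute (default 1600) or relative
(``offending_fraction``: a point is removed when more than that fraction
of the circumspheres it joined were offending). The absolute cutoff only
bites when points participate in thousands of samples; the relative mode
is the scale-free equivalent and is what the contamination tests use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, FittingError, InsufficientPointsError
from .extraction import SurfacePointSet
from .geometry import Point3, SphereModel, circumspheres

_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass(frozen=True)
class FitConfig:
    """Parameters of the robust fit; defaults follow the bench protocol."""

    n_samples: int = 80_000
    min_pair_separation: float = 2.0  # mm
    n_histogram_bins: int = 1000
    histogram_radius_range: tuple[float, float] = (0.0, 100.0)  # mm
    coarse_tolerance: float = 2.0  # mm
    fine_tolerance: float = 0.4  # mm, twice a 0.2 mm slice
    offending_count_threshold: int = 1600
    offending_fraction: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.coarse_tolerance <= 0 or self.fine_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.fine_tolerance >= self.coarse_tolerance:
            raise ValueError("fine_tolerance must be below coarse_tolerance")
        if self.min_pair_separation <= 0:
            raise ValueError("min_pair_separation must be positive")
        lo, hi = self.histogram_radius_range
        if not (0 <= lo < hi):
            raise ValueError("histogram_radius_range must be increasing")
        if self.offending_fraction is not None and not (
            0 < self.offending_fraction <= 1
        ):
            raise ValueError("offending_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FitReport:
    """Initial and final estimates plus point bookkeeping for one surface."""

    initial_radius: float
    initial_center: Point3
    final_radius: float
    final_center: Point3
    n_initial_points: int
    n_valid_points: int

    def __post_init__(self) -> None:
        if self.n_valid_points > self.n_initial_points:
            raise ValueError("n_valid_points cannot exceed n_initial_points")
        if self.initial_radius <= 0 or self.final_radius <= 0:
            raise ValueError("radii must be positive")


def _rng_for(cfg: FitConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.rng_seed)


def sample_quadruples(
    points: SurfacePointSet,
    cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw exactly ``cfg.n_samples`` admissible four-point index sets.

    Admissible means all six pairwise distances are at least
    ``cfg.min_pair_separation``; only valid points are used. Deterministic
    given the generator state (by default seeded from ``cfg.rng_seed``).

    Returns an (n_samples, 4) array of indices into ``points.points``.

    Raises
    ------
    InsufficientPointsError
        If fewer than four valid points exist, the valid points do not
        span the pair separation, or the rejection sampler cannot reach
        the requested count within a bounded number of draws.
    """
    rng = _rng_for(cfg, rng)
    valid_idx = np.flatnonzero(points.valid)
    if len(valid_idx) < 4:
        raise InsufficientPointsError(
            f"need at least 4 valid points, have {len(valid_idx)}"
        )
    pts = points.points[valid_idx]
    span = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
    if span < cfg.min_pair_separation:
        raise InsufficientPointsError(
            f"valid points span only {span:.3g} mm, below the "
            f"{cfg.min_pair_separation} mm pair separation"
        )
    sep2 = cfg.min_pair_separation**2
    need = cfg.n_samples
    batch = max(4096, min(need, 200_000))
    collected: list[np.ndarray] = []
    n_collected = 0
    max_draws = 400 * need + 1_000_000
    drawn = 0
    while n_collected < need:
        if drawn >= max_draws:
            raise InsufficientPointsError(
                "could not find enough admissible quadruples; points are "
                "too clustered for the requested pair separation"
            )
        cand = rng.integers(0, len(valid_idx), size=(batch, 4))
        drawn += batch
        keep = np.ones(batch, dtype=bool)
        for i, j in _PAIRS:
            d2 = np.sum((pts[cand[:, i]] - pts[cand[:, j]]) ** 2, axis=1)
            keep &= d2 >= sep2
            if not keep.any():
                break
        if keep.any():
            collected.append(cand[keep])
            n_collected += int(np.count_nonzero(keep))
    quads = np.concatenate(collected)[:need]
    return valid_idx[quads]


def initial_radius_estimate(
    points: SurfacePointSet,
    cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, Point3]:
    """Histogram-mode initialization of radius and center.

    Ties in the maximal histogram bin are broken toward the larger radius
    (spurious small radii from hole edges bias low).
    """
    quads = sample_quadruples(points, cfg, rng)
    centers, radii, ok = circumspheres(points.points[quads])
    lo, hi = cfg.histogram_radius_range
    ok = ok & (radii >= lo) & (radii < hi)
    if not np.any(ok):
        raise FittingError("all sampled quadruples were degenerate or out of range")
    counts, edges = np.histogram(
        radii[ok], bins=cfg.n_histogram_bins, range=(lo, hi)
    )
    imax = cfg.n_histogram_bins - 1 - int(np.argmax(counts[::-1]))
    initial_radius = 0.5 * (edges[imax] + edges[imax + 1])
    in_bin = ok & (radii >= edges[imax]) & (radii < edges[imax + 1])
    initial_center = np.median(centers[in_bin], axis=0)
    return float(initial_radius), initial_center


def prune_landmarks(
    points: SurfacePointSet,
    initial_radius: float,
    tolerance: float,
    cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> SurfacePointSet:
    """One pruning pass: count offending participations, invalidate points.

    A fresh batch of quadruples is sampled among the currently valid
    points; each quadruple whose circumsphere radius misses
    ``initial_radius`` by more than ``tolerance`` increments the offending
    count of its four members. Points whose count exceeds the configured
    cutoff (absolute, or relative to their participation count when
    ``cfg.offending_fraction`` is set) are marked invalid. Counts are
    per-pass. The valid set never grows.
    """
    if initial_radius <= 0:
        raise ValueError("initial_radius must be positive")
    rng = _rng_for(cfg, rng)
    out = points.copy()
    out.offending_count[:] = 0
    quads = sample_quadruples(points, cfg, rng)
    _, radii, ok = circumspheres(points.points[quads])
    bad = ok & (np.abs(radii - initial_radius) > tolerance)
    np.add.at(out.offending_count, quads[bad].ravel(), 1)
    if cfg.offending_fraction is not None:
        participation = np.zeros(len(out), dtype=np.int64)
        np.add.at(participation, quads[ok].ravel(), 1)
        with np.errstate(invalid="ignore"):
            over = out.offending_count > cfg.offending_fraction * participation
        over &= participation > 0
    else:
        over = out.offending_count > cfg.offending_count_threshold
    out.valid &= ~over
    if not out.valid.any():
        raise FittingError("pruning removed every point; check tolerances")
    return out


def least_squares_sphere(points: np.ndarray) -> SphereModel:
    """Geometric least-squares sphere: minimize sum of (|p - c| - r)^2.

    Initialized from the algebraic (linear) fit and refined over the
    center only (for a fixed center, the optimal radius is the mean
    distance). Exact on clean data; requires four or more non-coplanar
    points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points to fit a sphere")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = float(sv[0]) if sv[0] > 0 else 1.0
    if sv[2] <= 1e-9 * scale:
        raise DegenerateGeometryError("points are coplanar; sphere is undefined")

    # Algebraic (Coope) fit: |p|^2 = 2 c.p + (r^2 - |c|^2) is linear in (c, k).
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r2 = sol[3] + np.dot(c0, c0)
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit collapsed")

    def residuals(c: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(pts - c, axis=1)
        return d - d.mean()

    res = least_squares(residuals, c0, method="lm", xtol=1e-14, ftol=1e-14)
    center = res.x
    radius = float(np.linalg.norm(pts - center, axis=1).mean())
    return SphereModel(center=center, radius=radius)


def fit_sphere(
    points: SurfacePointSet, cfg: FitConfig
) -> tuple[SphereModel, FitReport]:
    """The full three-stage robust fit.

    Histogram initialization, coarse prune (±``coarse_tolerance``), fine
    prune (±``fine_tolerance``), then geometric least squares over the
    surviving valid points. Each stage samples a freshly seeded quadruple
    stream derived from ``cfg.rng_seed``, so the whole fit is
    deterministic.
    """
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.rng_seed).spawn(3)
    ]
    work = points.copy()
    r0, c0 = initial_radius_estimate(work, cfg, rng=streams[0])
    work = prune_landmarks(work, r0, cfg.coarse_tolerance, cfg, rng=streams[1])
    work = prune_landmarks(work, r0, cfg.fine_tolerance, cfg, rng=streams[2])
    model = least_squares_sphere(work.valid_points())
    report = FitReport(
        initial_radius=r0,
        initial_center=c0,
        final_radius=model.radius,
        final_center=model.center,
        n_initial_points=len(points),
        n_valid_points=work.n_valid,
    )
    return model, report
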