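"""Synthetic CT phantoms of an acetabular cup + femoral head with known truth.

The generator emulates the bench experiment used to validate the wear
pipeline: a hemispherical CoCr cup shell (with an apical dome hole and,
optionally, unused screw holes and a rough outer coating), a spherical
femoral head on a cylindrical stem, and a micrometer stage that translates
the head relative to the cup in sub-voxel steps. Volumes are rendered at a
nominal 0.2 mm isotropic voxel size with partial-volume blur (Gaussian
PSF) and additive Gaussian noise.

Voxelization is sub-voxel aware: each component contributes a smooth
occupancy (a clipped linear ramp of its signed surface distance over one
voxel), so a 0.05 mm head translation changes the rendered volume even at
0.2 mm voxels. This matters — the displacement design below steps the head
in 0.05 mm increments.

``MICROMETER_DISPLACEMENTS_MM`` holds the 14-scan displacement design of
the bench experiment (two scan-series identifier letters per row and the
(dx, dy, dz) micrometer setting in mm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .extraction import LandmarkSet, SphereLandmark
from .geometry import SphereModel
from .volume import CTVolume

#: The bench displacement design: (series-one id, series-two id, (dx, dy, dz) mm).
#: The first row is the reference scan (all micrometers at zero).
MICROMETER_DISPLACEMENTS_MM: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("T", "A", (0.000, 0.000, 0.000)),
    ("K", "G", (0.000, 0.000, 0.000)),
    ("X", "T", (0.050, 0.050, 0.050)),
    ("W", "F", (0.100, 0.100, 0.100)),
    ("N", "R", (0.150, 0.100, 0.100)),
    ("P", "M", (0.150, 0.150, 0.100)),
    ("A", "Y", (0.150, 0.150, 0.150)),
    ("R", "D", (0.200, 0.200, 0.200)),
    ("H", "W", (0.250, 0.250, 0.250)),
    ("Z", "C", (0.300, 0.300, 0.300)),
    ("D", "K", (0.350, 0.350, 0.350)),
    ("M", "P", (0.400, 0.400, 0.400)),
    ("E", "V", (0.450, 0.450, 0.450)),
    ("S", "Z", (0.500, 0.500, 0.500)),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and imaging parameters of one synthetic scan.

    Defaults are the bench-study conditions: a 54.2 mm cup, a 22.1 mm
    head, 0.2 mm isotropic voxels, PSF sigma of one voxel and noise of 5%
    of the metal intensity. Intensities are arbitrary units (metal 3000,
    background 0); any threshold between them works.
    """

    cup_outer_diameter: float = 54.2  # mm
    cup_shell_thickness: float = 4.0  # mm
    dome_hole_diameter: float = 8.0  # mm
    screw_hole_diameters: tuple[float, ...] = ()
    head_diameter: float = 22.1  # mm
    stem_radius: float = 5.0  # mm
    stem_length: float = 15.0  # mm, from the head center outward
    stem_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    cup_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    head_center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metal_intensity: float = 3000.0
    background_intensity: float = 0.0
    roughness_amplitude: float = 0.0  # mm, trabecular-mesh emulation
    psf_sigma: float = 0.2  # mm
    noise_sd: float = 150.0  # intensity units, added after blur
    voxel_spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    grid_shape: tuple[int, int, int] = (300, 300, 300)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cup_outer_diameter > self.head_diameter > 0):
            raise ConfigurationError(
                "need cup_outer_diameter > head_diameter > 0, got "
                f"{self.cup_outer_diameter} and {self.head_diameter}"
            )
        if not (0 < self.cup_shell_thickness < self.cup_outer_diameter / 2):
            raise ConfigurationError("cup_shell_thickness must be in (0, R_out)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel spacings must be positive")
        if any(int(n) < 8 for n in self.grid_shape):
            raise ConfigurationError("grid_shape axes must each be >= 8 voxels")
        if self.metal_intensity <= self.background_intensity:
            raise ConfigurationError("metal intensity must exceed background")
        if self.psf_sigma < 0 or self.noise_sd < 0 or self.roughness_amplitude < 0:
            raise ConfigurationError("sigma/noise/roughness must be nonnegative")
        inner = self.cup_outer_diameter / 2 - self.cup_shell_thickness
        if self.head_diameter / 2 >= inner:
            raise ConfigurationError("head does not fit inside the cup cavity")

    @property
    def cup_outer_radius(self) -> float:
        return self.cup_outer_diameter / 2.0

    @property
    def cup_inner_radius(self) -> float:
        return self.cup_outer_diameter / 2.0 - self.cup_shell_thickness

    @property
    def head_radius(self) -> float:
        return self.head_diameter / 2.0

    def cup_center(self) -> np.ndarray:
        """The cup center sits at the middle of the voxel grid."""
        shape = np.asarray(self.grid_shape, dtype=float)
        sp = np.asarray(self.voxel_spacing, dtype=float)
        return (shape - 1) * sp / 2.0

    def head_center(self) -> np.ndarray:
        return self.cup_center() + np.asarray(self.head_center_offset, dtype=float)

    def default_threshold(self) -> float:
        """Midway between background and metal — the bench convention."""
        return 0.5 * (self.metal_intensity + self.background_intensity)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic spheres and the applied displacement for one scan."""

    cup_sphere: SphereModel  # outer cup surface
    head_sphere: SphereModel
    displacement: tuple[float, float, float]  # mm, relative to the reference


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigurationError("axis vector must be nonzero")
    return v / n


def _check_fits(spec: PhantomSpec) -> None:
    """Reject implants that poke out of the grid (with a 2-voxel margin)."""
    sp = np.asarray(spec.voxel_spacing, dtype=float)
    lo = np.zeros(3) + 2 * sp
    hi = (np.asarray(spec.grid_shape) - 1) * sp - 2 * sp
    r_cup = spec.cup_outer_radius + spec.roughness_amplitude
    cup_c = spec.cup_center()
    head_c = spec.head_center()
    stem_tip = head_c + _unit(spec.stem_axis) * spec.stem_length
    extremes = [
        cup_c - r_cup, cup_c + r_cup,
        head_c - spec.head_radius, head_c + spec.head_radius,
        stem_tip - spec.stem_radius, stem_tip + spec.stem_radius,
    ]
    for p in extremes:
        if np.any(p < lo) or np.any(p > hi):
            raise ConfigurationError(
                "implant exceeds the voxel grid (or leaves less than a "
                "2-voxel margin); enlarge grid_shape or shrink the implant"
            )


def _screw_hole_directions(n: int, cup_axis: np.ndarray) -> np.ndarray:
    """Fixed screw-hole axes: 45 deg polar, azimuths evenly spread."""
    from .extraction import _orthonormal_basis

    basis = _orthonormal_basis(cup_axis)
    az = 2 * np.pi * np.arange(n) / max(n, 1) + 0.7
    local = np.column_stack(
        [np.cos(az) * np.sin(np.pi / 4), np.sin(az) * np.sin(np.pi / 4),
         np.full(n, np.cos(np.pi / 4))]
    )
    return local @ basis.T


def _smoothstep(d: np.ndarray, w: float) -> np.ndarray:
    """Occupancy ramp: 0 where d <= -w/2, 1 where d >= w/2, linear between."""
    d = np.asarray(d)
    out = d * d.dtype.type(1.0 / w) if d.dtype.kind == "f" else d / w
    out += out.dtype.type(0.5)
    np.clip(out, 0.0, 1.0, out=out)
    return out


def _smoothstep_(d: np.ndarray, w: float) -> np.ndarray:
    """In-place occupancy ramp (signed distance -> [0, 1])."""
    d *= d.dtype.type(1.0 / w)
    d += d.dtype.type(0.5)
    np.clip(d, 0.0, 1.0, out=d)
    return d


def _roughness(spec: PhantomSpec, u: list[np.ndarray], rng: np.random.Generator):
    """Band-limited radial perturbation of the outer cup surface.

    A small sum of random plane waves evaluated on the unit direction from
    the cup center, normalized to RMS ``roughness_amplitude``.
    """
    n_modes = 12
    k = rng.normal(size=(n_modes, 3)) * 4.0
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    amp = rng.normal(size=n_modes)
    delta = np.zeros_like(u[0])
    for m in range(n_modes):
        delta += amp[m] * np.cos(k[m, 0] * u[0] + k[m, 1] * u[1] + k[m, 2] * u[2]
                                 + phase[m])
    rms = np.sqrt(np.sum(amp**2) / 2.0)
    delta *= np.float32(spec.roughness_amplitude / rms)
    return delta


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render one CT-like volume and its analytic ground truth.

    Deterministic given ``spec.rng_seed``. Raises ``ConfigurationError``
    if the implant does not fit inside the grid with margin.
    """
    _check_fits(spec)
    rng = np.random.default_rng(spec.rng_seed)
    sp = np.asarray(spec.voxel_spacing, dtype=float)
    nx, ny, nz = (int(n) for n in spec.grid_shape)
    w = float(np.mean(sp))  # occupancy transition width, mm

    cup_c = spec.cup_center()
    head_c = spec.head_center()
    cup_axis = _unit(spec.cup_axis)
    stem_axis = _unit(spec.stem_axis)

    # Broadcastable world-coordinate axes relative to the cup center.
    # Everything downstream stays float32 (a 300^3 grid is ~10^7 voxels).
    dx = (np.arange(nx) * sp[0] - cup_c[0]).astype(np.float32).reshape(-1, 1, 1)
    dy = (np.arange(ny) * sp[1] - cup_c[1]).astype(np.float32).reshape(1, -1, 1)
    dz = (np.arange(nz) * sp[2] - cup_c[2]).astype(np.float32).reshape(1, 1, -1)

    f32 = np.float32
    shape = (nx, ny, nz)
    # Scratch buffers are allocated once and reused in place: repeatedly
    # materializing ~100 MB temporaries dominates runtime otherwise.
    occ = np.empty(shape, dtype=np.float32)
    tmp = np.empty(shape, dtype=np.float32)
    aux = np.empty(shape, dtype=np.float32)

    # Squared distance from the cup center -> aux (kept as r2).
    np.add(dx * dx + dy * dy, dz * dz, out=aux)  # (nx,ny,1)+(1,1,nz) -> full
    r2 = aux
    r = np.sqrt(r2, out=np.empty(shape, dtype=np.float32))
    # Axial coordinate along the cup axis (hemisphere side: a >= 0).
    a = np.empty(shape, dtype=np.float32)
    np.add(
        dx * f32(cup_axis[0]) + dy * f32(cup_axis[1]),
        dz * f32(cup_axis[2]),
        out=a,
    )

    # --- cup shell (accumulates into occ) --------------------------------
    if spec.roughness_amplitude > 0:
        safe_r = np.maximum(r, f32(1e-6))
        u = [dx / safe_r, dy / safe_r, dz / safe_r]
        r_out = f32(spec.cup_outer_radius) + _roughness(spec, u, rng)
        np.subtract(r_out, r, out=occ)
        del u, safe_r, r_out
    else:
        np.subtract(f32(spec.cup_outer_radius), r, out=occ)
    _smoothstep_(occ, w)
    np.subtract(r, f32(spec.cup_inner_radius), out=tmp)
    occ *= _smoothstep_(tmp, w)
    np.multiply(a, f32(1.0), out=tmp)
    occ *= _smoothstep_(tmp, w)
    # Apical dome hole: remove an axis-aligned cylinder through the shell.
    if spec.dome_hole_diameter > 0:
        np.multiply(a, a, out=tmp)
        np.subtract(r2, tmp, out=tmp)
        np.clip(tmp, 0.0, None, out=tmp)
        np.sqrt(tmp, out=tmp)  # distance to the cup axis
        np.subtract(f32(spec.dome_hole_diameter / 2), tmp, out=tmp)
        _smoothstep_(tmp, w)
        np.subtract(f32(1.0), tmp, out=tmp)
        occ *= tmp
    # Optional unused screw holes.
    if spec.screw_hole_diameters:
        dirs = _screw_hole_directions(len(spec.screw_hole_diameters), cup_axis)
        for d_hole, u_hole in zip(spec.screw_hole_diameters, dirs):
            np.add(
                dx * f32(u_hole[0]) + dy * f32(u_hole[1]),
                dz * f32(u_hole[2]),
                out=a,
            )
            np.multiply(a, a, out=tmp)
            np.subtract(r2, tmp, out=tmp)
            np.clip(tmp, 0.0, None, out=tmp)
            np.sqrt(tmp, out=tmp)
            np.subtract(f32(d_hole / 2), tmp, out=tmp)
            _smoothstep_(tmp, w)
            tmp *= _smoothstep_(a, w)  # only the hemisphere-side patch
            np.subtract(f32(1.0), tmp, out=tmp)
            occ *= tmp

    # --- femoral head (squared distance -> r2 buffer, reused) ------------
    hx, hy, hz = (f32(v) for v in head_c - cup_c)
    small = (dx - hx) ** 2 + (dy - hy) ** 2  # (nx, ny, 1): cheap
    np.add(small, (dz - hz) ** 2, out=r2)
    rh = np.sqrt(r2, out=r)  # cup r no longer needed
    np.subtract(f32(spec.head_radius), rh, out=tmp)
    np.maximum(occ, _smoothstep_(tmp, w), out=occ)

    # --- stem (capped cylinder from the head center outward) -------------
    b = a  # reuse
    np.add(
        (dx - hx) * f32(stem_axis[0]) + (dy - hy) * f32(stem_axis[1]),
        (dz - hz) * f32(stem_axis[2]),
        out=b,
    )
    np.multiply(b, b, out=tmp)
    np.subtract(r2, tmp, out=tmp)
    np.clip(tmp, 0.0, None, out=tmp)
    np.sqrt(tmp, out=tmp)  # radial distance from the stem axis
    np.subtract(f32(spec.stem_radius), tmp, out=tmp)
    _smoothstep_(tmp, w)
    np.multiply(b, f32(1.0), out=r2)
    tmp *= _smoothstep_(r2, w)
    np.subtract(f32(spec.stem_length), b, out=r2)
    tmp *= _smoothstep_(r2, w)
    np.maximum(occ, tmp, out=occ)
    del rh, b, a, r, r2, aux, tmp, dx, dy, dz, small

    intensities = occ
    intensities *= f32(spec.metal_intensity - spec.background_intensity)
    intensities += f32(spec.background_intensity)

    if spec.psf_sigma > 0:
        gaussian_filter(
            intensities, sigma=spec.psf_sigma / sp, output=intensities
        )
    if spec.noise_sd > 0:
        noise = rng.standard_normal(intensities.shape, dtype=np.float32)
        noise *= np.float32(spec.noise_sd)
        intensities += noise
        del noise

    vol = CTVolume(intensities=intensities, spacing=sp, origin=np.zeros(3))
    truth = GroundTruth(
        cup_sphere=SphereModel(center=cup_c, radius=spec.cup_outer_radius),
        head_sphere=SphereModel(center=head_c, radius=spec.head_radius),
        displacement=tuple(float(v) for v in spec.head_center_offset),
    )
    return vol, truth


def generate_series(
    base_spec: PhantomSpec,
    displacements: list[tuple[float, float, float]],
) -> list[tuple[CTVolume, GroundTruth]]:
    """One volume per displacement; scan ``i`` uses seed ``base_seed + i``.

    The first entry is conventionally the (0, 0, 0) reference. All scans
    share the base geometry; the displacement translates the head only (a
    rigid translation, which is how the micrometer stage is modelled).
    """
    if len(displacements) == 0:
        raise ConfigurationError("displacement list must be nonempty")
    out = []
    for i, d in enumerate(displacements):
        d = tuple(float(v) for v in np.asarray(d, dtype=float).reshape(3))
        base = np.asarray(base_spec.head_center_offset, dtype=float)
        spec_i = replace(
            base_spec,
            head_center_offset=tuple(base + d),
            rng_seed=base_spec.rng_seed + i,
        )
        vol, truth = generate_phantom(spec_i)
        out.append((vol, replace(truth, displacement=d)))
    return out


def auto_landmarks(truth: GroundTruth, spec: PhantomSpec) -> LandmarkSet:
    """Synthesize the seven-landmark protocol from ground truth.

    Stands in for the human operator when testing on phantoms: three rim
    points on the cup's equatorial plane, the apical dome-hole point, an
    offset point 5–10 mm outward along the cup axis, the stem-junction
    sphere and a head-enclosing sphere at least two voxels larger than the
    head.
    """
    from .extraction import _orthonormal_basis

    cup_c = truth.cup_sphere.center
    r_out = truth.cup_sphere.radius
    axis = _unit(spec.cup_axis)
    basis = _orthonormal_basis(axis)
    e1, e2 = basis[:, 0], basis[:, 1]
    rim_angles = np.deg2rad([15.0, 135.0, 255.0])
    rim = np.stack(
        [cup_c + r_out * (np.cos(t) * e1 + np.sin(t) * e2) for t in rim_angles]
    )
    apex = cup_c + r_out * axis
    offset_pt = apex + 7.5 * axis  # 5-10 mm outward along the axis

    head_c = truth.head_sphere.center
    head_r = truth.head_sphere.radius
    stem_axis = _unit(spec.stem_axis)
    junction = SphereLandmark(
        center=head_c + stem_axis * head_r, radius=spec.stem_radius + 2.0
    )
    enc_radius = head_r + max(1.5, 2.0 * float(np.max(spec.voxel_spacing)))
    enclosing = SphereLandmark(center=head_c, radius=enc_radius)
    return LandmarkSet(
        cup_rim=rim,
        cup_apex=apex,
        cup_offset=offset_pt,
        stem_junction=junction,
        head_enclosing=enclosing,
    )
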