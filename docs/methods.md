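# Methods

## Measurement model

Both implant components are modelled as spheres in world millimetres: the
acetabular cup by its outer hemispherical shell surface, the femoral head
by its articular surface. Liner wear appears as a change in the vector
between the two sphere centers. Because the cup and the whole phantom may
move rigidly between scans, the series measurement reports, for scan *i*
relative to the reference scan *0*,

    measured_i = || v_i − v_0 ||,   v = c_head − c_cup,

the magnitude of the head's displacement relative to the cup. When the
reference is concentric (as in the default phantom) this coincides with
the plain center distance; in general it is the quantity that is invariant
to common rigid motion of the pair. `cup_head_separation` itself is the
plain center distance, matching the definition of the wear proxy.

The expected value for each scan is the Euclidean norm of the micrometer
setting (dx, dy, dz). The displacement stage is modelled as a rigid
translation of the head (plus stem) only; the cup stays fixed.

## Surface extraction

The ray search is deliberately resolution-independent:

* directions: Fibonacci-spiral samples (hemisphere on the apex side of
  the rim plane for the cup, full sphere for the head), default 4,000 —
  deterministic and near-uniform;
* each ray starts at 1.2× the starting radius from the estimated cup
  center (apex projected onto the rim plane) or on the head-enclosing
  sphere, and marches inward in steps of half the smallest voxel spacing
  with trilinear interpolation;
* a surface point is the **first sample** of the first run of
  `min_run_length` (default 3) consecutive above-threshold samples, with
  no sub-voxel edge refinement; isolated above-threshold voxels therefore
  never produce points. A ray whose very first sample is already metal
  has no outside-in crossing and is discarded — this is what makes a
  too-small head-enclosing landmark fail loudly instead of silently
  producing a sphere of start points.
* cup rays stop after 60% of the starting radius (screw-hole protection);
  head rays whose segment would intersect the stem-junction landmark
  sphere are discarded before marching.

The first-sample convention quantizes each point inward by up to one step
(expected half a step, i.e. 0.05 mm at defaults). This is a pure radial
bias at near-normal incidence: it shrinks fitted diameters by ≈0.1 mm but
leaves centers — and hence separations — essentially unbiased, which is
why the pipeline resolves 0.05 mm head displacements on 0.2 mm voxels.
The starting radius uses the apical-dome point by default; the offset
landmark can be selected instead (`radius_landmark="offset"`), since both
conventions appear in practice.

## Robust sphere fitting

Four-point subsets with all pairwise distances ≥2 mm (rejection-sampled,
deterministic per seed) give exact circumspheres via a 3×3 linear system;
quadruples with tetrahedron volume <1e-6 mm³ are discarded as degenerate.
The radius histogram uses 1000 uniform bins over 0–100 mm (0.1 mm bins,
covering all plausible implant radii — integer-millimetre bins would be
too coarse for the precision achieved); ties in the maximal bin break
toward the larger radius because hole-edge artifacts bias small. The
initial center is the component-wise median of the in-bin circumsphere
centers. Each pruning pass re-samples a fresh, independently seeded
quadruple stream among the currently valid points and counts, per point,
offending participations (circumsphere radius off the initial radius by
more than the pass tolerance: ±2 mm coarse, ±0.4 mm fine, i.e. twice a
0.2 mm slice).

The offending-count cutoff is absolute by default (1,600). At desk-scale
sampling budgets (80,000 quadruples over a few thousand points, mean
participation ≈20–80) an absolute cutoff of 1,600 never fires, so default
fits rely on the final estimator's tolerance of the small (≲1%) hole-edge
contamination the phantoms produce. The scale-free alternative is
`offending_fraction`: a point is removed when more than that fraction of
its participations offended. The contamination tests use fractions of
0.7–0.93 depending on the planted outlier share; the fraction needed
grows with the contamination level because a clean point's quadruple is
itself contaminated with probability 1−(1−ρ)³ at outlier share ρ.

The final estimator is geometric least squares, min Σ(|p−c|−r)², solved
over the center only (the optimal radius for a fixed center is the mean
distance), initialized from the algebraic (Coope) fit and refined by
Levenberg–Marquardt. On outlier-free data no point is ever pruned and the
robust fit reduces exactly to this estimator — the oracle-equivalence
tests exploit that.

## Statistics

* Summary statistics: mean, median, SD (n−1), CV = 100·SD/mean, and a
  Student-t confidence interval (default 99%).
* Agreement regression: OLS of measured on expected separation
  (statsmodels); a perfect instrument gives the 45° line.
* Repeatability: for paired repeat measurements, s_r² = Σd²/(2n) over the
  within-pair differences d, and the coefficient r = 2.77·s_r — the ISO
  5725 convention (2.77 = 1.96·√2 rounded), bounding |d| of a future pair
  with ≈95% probability. The constant is a convention choice; the signed
  differences are also summarized so bias is visible separately.

## Synthetic phantom

The generator emulates a bench micrometer experiment: a CoCr-like cup
shell (outer diameter 54.2 mm, shell 4 mm, 8 mm apical dome hole,
optional 45°-inclined unused screw holes, optional band-limited radial
roughness emulating a 0.3 mm trabecular coating), a 22.1 mm head and a
5 mm-radius stem, at 0.2 mm isotropic voxels. Intensities are arbitrary
units — metal 3000, background 0, threshold midway at 1500 — since only
the contrast matters. Imaging physics is reduced to a Gaussian PSF
(σ = 0.2 mm, one voxel) applied to a sub-voxel-accurate occupancy map
(clipped linear ramp of the signed surface distance over one voxel),
followed by additive white Gaussian noise (SD 150 = 5% of metal). Noise
is added after the blur, so it is unsmoothed. Scan *i* of a series uses
seed `base_seed + i` — reproducible, independent noise per scan.

The default grid is 300³ (a 60 mm field of view): the smallest grid that
holds the 54.2 mm cup with a safety margin at 0.2 mm spacing while
keeping a full 14-scan series around half a minute of simulation. The
auto-landmark generator stands in for the human operator, emitting the
seven-landmark protocol from ground truth; a seeded ±1 mm jitter option
emulates operator variability (the pipeline's separation output moves by
well under 0.05 mm, since landmarks only gate the search).

What the phantom does **not** emulate: beam hardening, metal streak
artifacts, scatter, scanner-specific reconstruction kernels, patient
motion, and a physically seated head (displacements are free rigid
translations). Passing the end-to-end tests therefore demonstrates the
geometric and statistical machinery at realistic resolution, blur and
noise — not robustness to clinical artifact load.

## Numerical choices and degenerate inputs

* All geometry in world mm; voxel (i, j, k) maps to
  `origin + (i·sx, j·sy, k·sz)` at the voxel center; direction cosines
  beyond axis scaling are not interpreted.
* Colinear rim points, coplanar quadruples, an apex on the rim plane, a
  sphere fit on coplanar points: explicit degenerate-geometry errors, with
  tolerances 1e-9 mm² (triangle area) and 1e-6 mm³ (tetrahedron volume).
* Interpolation outside the grid returns the volume minimum, so rays may
  legally start outside the field of view.
* An empty extraction result (wrong threshold or landmarks) raises an
  empty-surface error rather than returning an empty set; fewer than 500
  head points triggers a warning.
* Output tables round lengths to 3 decimals (micron precision); full
  precision is kept in memory.

## Problem sizes used in validation

The acceptance run simulates and fits all 14 scans of the displacement
design at the full 300³/0.2 mm bench conditions. Unit tests use a
geometrically similar 20 mm cup / 8 mm head phantom on a 128³ grid, which
preserves every geometric feature (rim, dome hole, stem shadow) at a
fraction of the cost; sphere-fitting sampling budgets in tests are
20,000–40,000 quadruples where the estimator's behaviour, not the budget,
is under test.
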