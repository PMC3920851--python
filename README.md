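# ctwear

Automated measurement of polyethylene liner wear in total hip
arthroplasty (THA) from CT volumes.

## The problem

A THA implant pairs a hemispherical metal acetabular cup (with a
polyethylene liner) and a spherical femoral head. As the liner wears, the
head's center migrates toward the cup's center; detecting that migration
early — at the 0.1 mm scale, against typical wear rates of 0.005–0.04
mm/year — lets surgeons replace only the liner instead of revising the
whole joint. The polyethylene itself is invisible at metal thresholds, so
the wear proxy is **CupHeadSeparation**: the Euclidean distance between
the center of the sphere fitted to the cup's outer surface and the center
of the sphere fitted to the head,

```
CupHeadSeparation = || c_cup − c_head ||            (mm)
```

tracked relative to a reference scan.

## The method

Seven operator landmarks gate a fully automatic pipeline:

1. **Landmarks** — three points on the cup rim (defining the rim plane),
   one point in the apical dome hole, one point shifted 5–10 mm outward
   along the cup axis, a sphere around the head/stem junction, and a
   sphere enclosing the head.
2. **Surface extraction** — rays are cast inward (over the apex-side
   hemisphere for the cup; from the enclosing sphere for the head),
   sampling the volume by trilinear interpolation and recording the first
   position where the intensity exceeds the metal threshold for ≥3
   consecutive steps. Cup rays are capped at 60% of the starting radius
   (the rim-plane-to-apex distance) so unused screw holes are skipped;
   head rays that would cross the stem-junction sphere are discarded.
3. **Robust sphere fitting** — 80,000 random four-point subsets (every
   pair ≥2 mm apart) give candidate circumspheres; a 1000-bin radius
   histogram picks the initial radius; two per-point pruning passes (±2 mm,
   then ±2 slice thicknesses) remove points that repeatedly contribute
   off-radius circumspheres; a geometric least-squares fit
   (min Σ(|p−c|−r)²) of the survivors gives the final center and radius.
4. **Wear analysis** — per-scan separation vs the expected value from the
   micrometer settings, ordinary least squares against the 45° line,
   summary statistics, and the ISO 5725 repeatability coefficient
   r = 2.77·s_r.

A synthetic phantom generator renders CT-like volumes of the full
geometry (cup shell with dome hole, head, stem) with sub-voxel-accurate
partial volume, Gaussian PSF blur and noise, so the whole pipeline is
validated end to end against known ground truth.

## Worked example

```python
import ctwear as cw

spec = cw.PhantomSpec(rng_seed=7)            # 54.2 mm cup, 22.1 mm head,
                                             # 0.2 mm voxels, 300^3 grid
disps = [row[2] for row in cw.MICROMETER_DISPLACEMENTS_MM]
result = cw.run_displacement_series(spec, disps)

for rec in result.records[:3]:
    print(rec.scan_id, round(rec.measured_separation, 4),
          rec.expected_separation, round(rec.difference, 4))
print("max |error|:", round(result.max_abs_difference, 4), "mm")
print("cup diameter:", result.cup_diameters.mean().round(3), "mm")
```

prints (seed 7):

```
scan00 0.0 0.0 0.0
scan01 0.0046 0.0 0.0046
scan02 0.0872 0.08660254037844388 0.0005
max |error|: 0.0066 mm
cup diameter: 54.044 mm
```

i.e. across the 14-scan displacement series every measured separation is
within 0.0066 mm of the micrometer truth (well inside the ±0.1 mm target),
and the fitted cup diameter is stable to a few microns across scans (the
~0.15 mm low bias against the nominal 54.2 mm diameter is the known
half-step quantization of the first-sample surface convention; it is
common to all scans and cancels in separations).

The same pipeline is exposed as a CLI:

```sh
ctwear simulate --out-dir scans --table1 --seed 7
ctwear fit --volume scans/scan_T.nii.gz --landmarks scans/landmarks_T.csv \
           --threshold 1500 --out results.csv
# ... one fit per scan, then:
ctwear measure --results results.csv --truth scans/truth.csv --out wear.csv
ctwear analyze --wear wear.csv --out summary.json --plot wear.png
```

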