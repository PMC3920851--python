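"""Volume, landmark and results-table I/O.

Volumes: NIfTI through nibabel; NRRD/MetaImage (and DICOM series
directories) through SimpleITK. Spacing must be present in the file —
a volume without explicit voxel spacing is a format error, never silently
assumed to be 1 mm. Direction cosines beyond the axis scalings are not
interpreted.

Tables are plain CSV via pandas:

* landmarks — columns ``name, x_mm, y_mm, z_mm, radius_mm`` with the seven
  protocol rows (rim1, rim2, rim3, apex, offset, stem_junction,
  head_enclosing); radius is empty for point landmarks;
* sphere-fit results — one row per fitted surface with the field order
  ``scan_id, initial_radius, initial_center x/y/z, final_radius,
  final_center x/y/z`` (all mm);
* wear records — ``scan_id, measured_mm, expected_mm, difference_mm``.

Lengths in output tables are written with 3 decimals (micrometer
precision); full precision is kept in memory.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .analysis import RegressionResult, RepeatabilityResult, SummaryStats, WearRecord
from .errors import LandmarkValidationError, VolumeFormatError
from .extraction import LandmarkSet, SphereLandmark
from .fitting import FitReport
from .geometry import SphereModel
from .volume import CTVolume

_POINT_LANDMARKS = ("rim1", "rim2", "rim3", "apex", "offset")
_SPHERE_LANDMARKS = ("stem_junction", "head_enclosing")
LANDMARK_NAMES = _POINT_LANDMARKS + _SPHERE_LANDMARKS

RESULTS_COLUMNS = [
    "scan_id",
    "initial_radius",
    "initial_center_x",
    "initial_center_y",
    "initial_center_z",
    "final_radius",
    "final_center_x",
    "final_center_y",
    "final_center_z",
]


# --------------------------------------------------------------------------
# volumes


def _nifti_read(path: str) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if zooms.size != 3 or np.any(~np.isfinite(zooms)) or np.any(zooms <= 0):
        raise VolumeFormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return CTVolume(intensities=data, spacing=zooms, origin=origin)


def _nifti_write(vol: CTVolume, path: str) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32), affine), path)


def _assert_header_has_spacing(path: str) -> None:
    """NRRD / MetaImage headers are text; refuse files without spacing."""
    with open(path, "rb") as fh:
        head = fh.read(8192).decode("latin-1", errors="replace").lower()
    keys = ("spacings", "space directions", "elementspacing", "elementsize")
    if not any(k in head for k in keys):
        raise VolumeFormatError(
            f"{path}: no voxel spacing in header; refusing to assume 1 mm"
        )


def _sitk_read(path: str) -> CTVolume:
    import SimpleITK as sitk

    if os.path.isdir(path):  # DICOM series directory
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(path)
        if not files:
            raise VolumeFormatError(f"{path}: no DICOM series found")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        _assert_header_has_spacing(path)
        img = sitk.ReadImage(path)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if spacing.size != 3 or np.any(spacing <= 0):
        raise VolumeFormatError(f"{path}: invalid voxel spacing {spacing}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got {arr.ndim}-D")
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    return CTVolume(intensities=data, spacing=spacing, origin=origin)


def _sitk_write(vol: CTVolume, path: str) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(
            np.asarray(vol.intensities, dtype=np.float32).transpose(2, 1, 0)
        )
    )
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, path, useCompression=True)


def read_volume(path: str) -> CTVolume:
    """Load a CT volume (NIfTI, NRRD, MetaImage, or a DICOM directory)."""
    p = str(path)
    if os.path.isdir(p):
        return _sitk_read(p)
    lower = p.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return _nifti_read(p)
    if lower.endswith((".nrrd", ".nhdr", ".mha", ".mhd")):
        return _sitk_read(p)
    raise VolumeFormatError(f"unrecognized volume format: {path}")


def write_volume(vol: CTVolume, path: str) -> None:
    p = str(path)
    lower = p.lower()
    if lower.endswith((".nii", ".nii.gz")):
        _nifti_write(vol, p)
    elif lower.endswith((".nrrd", ".nhdr", ".mha", ".mhd")):
        _sitk_write(vol, p)
    else:
        raise VolumeFormatError(f"unrecognized volume format: {path}")


# --------------------------------------------------------------------------
# landmarks


def write_landmarks(lm: LandmarkSet, path: str) -> None:
    rows = []
    for name, p in zip(_POINT_LANDMARKS, [*lm.cup_rim, lm.cup_apex, lm.cup_offset]):
        rows.append({"name": name, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                     "radius_mm": np.nan})
    for name, sl in zip(_SPHERE_LANDMARKS, (lm.stem_junction, lm.head_enclosing)):
        rows.append({"name": name, "x_mm": sl.center[0], "y_mm": sl.center[1],
                     "z_mm": sl.center[2], "radius_mm": sl.radius})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_landmarks(path: str) -> LandmarkSet:
    """Read and validate the seven-landmark CSV.

    Raises ``LandmarkValidationError`` naming the offending/missing rows.
    """
    df = pd.read_csv(path)
    required = {"name", "x_mm", "y_mm", "z_mm", "radius_mm"}
    if not required.issubset(df.columns):
        raise LandmarkValidationError(
            f"{path}: landmark CSV must have columns {sorted(required)}"
        )
    by_name = {str(r["name"]): r for _, r in df.iterrows()}
    missing = [n for n in LANDMARK_NAMES if n not in by_name]
    if missing:
        raise LandmarkValidationError(f"{path}: missing landmark rows {missing}")
    extra = [n for n in by_name if n not in LANDMARK_NAMES]
    if extra:
        raise LandmarkValidationError(f"{path}: unexpected landmark rows {extra}")

    def pt(name: str) -> np.ndarray:
        r = by_name[name]
        return np.array([r["x_mm"], r["y_mm"], r["z_mm"]], dtype=float)

    spheres = {}
    for name in _SPHERE_LANDMARKS:
        radius = by_name[name]["radius_mm"]
        if pd.isna(radius) or float(radius) <= 0:
            raise LandmarkValidationError(
                f"{path}: landmark '{name}' requires a positive radius_mm"
            )
        spheres[name] = SphereLandmark(center=pt(name), radius=float(radius))
    return LandmarkSet(
        cup_rim=np.stack([pt("rim1"), pt("rim2"), pt("rim3")]),
        cup_apex=pt("apex"),
        cup_offset=pt("offset"),
        stem_junction=spheres["stem_junction"],
        head_enclosing=spheres["head_enclosing"],
    )


# --------------------------------------------------------------------------
# results / wear tables


def surface_points_to_csv(points: np.ndarray, path: str) -> None:
    pd.DataFrame(points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False, float_format="%.4f"
    )


def results_rows(scan_id: str, surface: str, report: FitReport) -> dict:
    return {
        "scan_id": f"{scan_id}_{surface}",
        "initial_radius": report.initial_radius,
        "initial_center_x": report.initial_center[0],
        "initial_center_y": report.initial_center[1],
        "initial_center_z": report.initial_center[2],
        "final_radius": report.final_radius,
        "final_center_x": report.final_center[0],
        "final_center_y": report.final_center[1],
        "final_center_z": report.final_center[2],
    }


def write_results_csv(rows: Iterable[dict], path: str, append: bool = False) -> None:
    df = pd.DataFrame(list(rows))[RESULTS_COLUMNS]
    mode = "a" if append and os.path.exists(path) else "w"
    df.to_csv(path, index=False, float_format="%.3f", mode=mode,
              header=(mode == "w"))


def read_results_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: results CSV missing columns {missing}")
    return df


def final_sphere(df: pd.DataFrame, scan_id: str, surface: str) -> SphereModel:
    row = df[df["scan_id"] == f"{scan_id}_{surface}"]
    if len(row) != 1:
        raise ValueError(f"expected exactly one row for {scan_id}_{surface}")
    r = row.iloc[0]
    return SphereModel(
        center=np.array([r["final_center_x"], r["final_center_y"],
                         r["final_center_z"]]),
        radius=float(r["final_radius"]),
    )


def write_wear_csv(records: Iterable[WearRecord], path: str) -> None:
    pd.DataFrame(
        [
            {
                "scan_id": r.scan_id,
                "measured_mm": r.measured_separation,
                "expected_mm": r.expected_separation,
                "difference_mm": r.difference,
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.3f")


def read_wear_csv(path: str) -> list[WearRecord]:
    df = pd.read_csv(path)
    return [
        WearRecord.from_measurement(
            str(r["scan_id"]), float(r["measured_mm"]), float(r["expected_mm"])
        )
        for _, r in df.iterrows()
    ]


def write_truth_csv(
    scan_ids: Sequence[str],
    displacements: Sequence[tuple[float, float, float]],
    path: str,
) -> None:
    from .analysis import expected_separation

    rows = [
        {
            "scan_id": sid,
            "dx_mm": d[0],
            "dy_mm": d[1],
            "dz_mm": d[2],
            "expected_separation_mm": expected_separation(*d),
        }
        for sid, d in zip(scan_ids, displacements)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.3f")


def read_truth_csv(path: str) -> tuple[list[str], list[tuple[float, float, float]]]:
    df = pd.read_csv(path)
    ids = [str(s) for s in df["scan_id"]]
    disps = [
        (float(r["dx_mm"]), float(r["dy_mm"]), float(r["dz_mm"]))
        for _, r in df.iterrows()
    ]
    return ids, disps


def _stats_dict(s: SummaryStats) -> dict:
    return {
        "n": s.n,
        "mean": s.mean,
        "median": s.median,
        "sd": s.sd,
        "cv_percent": s.coefficient_of_variation,
        "ci_lower": s.ci_lower,
        "ci_upper": s.ci_upper,
        "confidence": s.confidence,
    }


def write_summary_json(
    path: str,
    regression: RegressionResult | None = None,
    difference_stats: SummaryStats | None = None,
    repeat: RepeatabilityResult | None = None,
    extra: dict | None = None,
) -> None:
    out: dict = dict(extra or {})
    if regression is not None:
        out["regression"] = {
            "slope": regression.slope,
            "intercept": regression.intercept,
            "slope_se": regression.slope_se,
            "intercept_se": regression.intercept_se,
            "slope_p": regression.slope_p,
            "intercept_p": regression.intercept_p,
            "residual_sd": regression.residual_sd,
            "f_value": regression.f_value,
            "n": regression.n,
        }
    if difference_stats is not None:
        out["difference_stats"] = _stats_dict(difference_stats)
    if repeat is not None:
        out["repeatability"] = {
            "coefficient": repeat.coefficient,
            "within_pair_sd": repeat.within_pair_sd,
            "n_pairs": repeat.n_pairs,
            "difference_stats": _stats_dict(repeat.difference_stats),
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
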