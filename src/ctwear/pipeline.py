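"""End-to-end orchestration: phantom -> landmarks -> surfaces -> spheres -> wear.

`fit_scan` runs extraction plus robust fitting for both surfaces of one
volume. `run_displacement_series` renders a whole displacement series
(generating each phantom on the fly to bound memory), fits every scan and
reports each scan's separation relative to the reference scan.

Separation convention: per-scan CupHeadSeparation is the distance between
fitted centers; for a series the measured value of scan *i* is
``| v_i - v_ref |`` with ``v = head_center - cup_center``, i.e. the
magnitude of the head's displacement relative to the cup since the
reference scan. When the reference is concentric (the default phantom)
this coincides with the plain center distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .analysis import WearRecord, expected_separation
from .extraction import (
    ExtractionConfig,
    LandmarkSet,
    extract_cup_surface,
    extract_head_surface,
)
from .fitting import FitConfig, FitReport, fit_sphere
from .geometry import SphereModel
from .phantom import GroundTruth, PhantomSpec, auto_landmarks, generate_phantom
from .volume import CTVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanFit:
    """Fitted cup and head spheres (with reports) for one scan."""

    scan_id: str
    cup: SphereModel
    cup_report: FitReport
    head: SphereModel
    head_report: FitReport

    @property
    def separation_vector(self) -> np.ndarray:
        return self.head.center - self.cup.center


@dataclass(frozen=True)
class SeriesResult:
    """All per-scan fits and wear records for one displacement series."""

    fits: list[ScanFit]
    records: list[WearRecord]
    truths: list[GroundTruth]

    @property
    def cup_diameters(self) -> np.ndarray:
        return np.array([f.cup.diameter for f in self.fits])

    @property
    def head_diameters(self) -> np.ndarray:
        return np.array([f.head.diameter for f in self.fits])

    @property
    def max_abs_difference(self) -> float:
        return max(abs(r.difference) for r in self.records)


def fit_scan(
    vol: CTVolume,
    landmarks: LandmarkSet,
    ext_cfg: ExtractionConfig,
    fit_cfg: FitConfig,
    scan_id: str = "scan",
) -> ScanFit:
    """Extract both surfaces and fit a sphere to each.

    The head fit uses an independently derived random stream so cup and
    head estimates never share quadruple draws.
    """
    cup_pts = extract_cup_surface(vol, landmarks, ext_cfg)
    head_pts = extract_head_surface(vol, landmarks, ext_cfg)
    log.debug(
        "%s: %d cup points, %d head points", scan_id, len(cup_pts), len(head_pts)
    )
    cup_model, cup_report = fit_sphere(cup_pts, fit_cfg)
    head_cfg = replace(fit_cfg, rng_seed=fit_cfg.rng_seed + 1_000_003)
    head_model, head_report = fit_sphere(head_pts, head_cfg)
    return ScanFit(
        scan_id=scan_id,
        cup=cup_model,
        cup_report=cup_report,
        head=head_model,
        head_report=head_report,
    )


def measure_series(
    fits: Sequence[ScanFit],
    displacements: Sequence[tuple[float, float, float]],
    reference_index: int = 0,
) -> list[WearRecord]:
    """Wear records for a fitted series relative to its reference scan."""
    if len(fits) != len(displacements):
        raise ValueError("one displacement triple is required per fitted scan")
    v_ref = fits[reference_index].separation_vector
    d_ref = np.asarray(displacements[reference_index], dtype=float)
    records = []
    for fit, disp in zip(fits, displacements):
        rel = np.asarray(disp, dtype=float) - d_ref
        measured = float(np.linalg.norm(fit.separation_vector - v_ref))
        expected = expected_separation(*rel)
        records.append(WearRecord.from_measurement(fit.scan_id, measured, expected))
    return records


def run_displacement_series(
    base_spec: PhantomSpec,
    displacements: Sequence[tuple[float, float, float]],
    scan_ids: Sequence[str] | None = None,
    threshold: float | None = None,
    ext_cfg: ExtractionConfig | None = None,
    fit_cfg: FitConfig | None = None,
    landmark_perturbation_mm: float = 0.0,
) -> SeriesResult:
    """Simulate, landmark, extract, fit and measure a displacement series.

    Scan ``i`` is rendered with seed ``base_spec.rng_seed + i`` and its
    head displaced by ``displacements[i]`` from the base position; the
    first scan is the reference. ``threshold`` defaults midway between
    background and metal. A nonzero ``landmark_perturbation_mm`` jitters
    the auto-generated landmarks (seeded), emulating operator variability.
    """
    if len(displacements) == 0:
        raise ValueError("displacement list must be nonempty")
    if scan_ids is None:
        scan_ids = [f"scan{i:02d}" for i in range(len(displacements))]
    if len(scan_ids) != len(displacements):
        raise ValueError("need one scan id per displacement")
    if threshold is None:
        threshold = base_spec.default_threshold()
    if ext_cfg is None:
        ext_cfg = ExtractionConfig(threshold=threshold)
    if fit_cfg is None:
        fit_cfg = FitConfig(rng_seed=base_spec.rng_seed)

    base_offset = np.asarray(base_spec.head_center_offset, dtype=float)
    fits: list[ScanFit] = []
    truths: list[GroundTruth] = []
    for i, (sid, disp) in enumerate(zip(scan_ids, displacements)):
        disp = tuple(float(v) for v in np.asarray(disp, dtype=float).reshape(3))
        spec_i = replace(
            base_spec,
            head_center_offset=tuple(base_offset + disp),
            rng_seed=base_spec.rng_seed + i,
        )
        vol, truth = generate_phantom(spec_i)
        truth = replace(truth, displacement=disp)
        lm = auto_landmarks(truth, spec_i)
        if landmark_perturbation_mm > 0:
            from .extraction import perturb_landmarks

            lm_rng = np.random.default_rng(base_spec.rng_seed + 7919 * (i + 1))
            lm = perturb_landmarks(lm, landmark_perturbation_mm, lm_rng)
        scan_fit_cfg = replace(fit_cfg, rng_seed=fit_cfg.rng_seed + 2 * i)
        fits.append(fit_scan(vol, lm, ext_cfg, scan_fit_cfg, scan_id=sid))
        truths.append(truth)
        log.info(
            "fitted %s: cup d=%.3f mm, head d=%.3f mm",
            sid,
            fits[-1].cup.diameter,
            fits[-1].head.diameter,
        )
        del vol  # volumes are ~100 MB each; keep only one alive
    records = measure_series(fits, displacements)
    return SeriesResult(fits=fits, records=records, truths=truths)
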