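"""Wear metrics and their statistics.

The wear proxy is CupHeadSeparation: the Euclidean distance between the
fitted cup-sphere center and head-sphere center. For a displacement
series, each scan's measured separation (relative to the reference scan)
is compared with the expected separation computed from the micrometer
settings, and the agreement is summarized by an ordinary least-squares
regression against the 45-degree line, summary statistics of the
differences, and a repeatability coefficient for paired repeat
measurements (r = 2.77 * s_r with s_r the within-pair standard deviation,
the ISO 5725 convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .geometry import SphereModel


@dataclass(frozen=True)
class WearRecord:
    """One scan's separation versus the micrometer expectation (mm)."""

    scan_id: str
    measured_separation: float
    expected_separation: float
    difference: float  # measured - expected

    def __post_init__(self) -> None:
        if abs(self.difference - (self.measured_separation - self.expected_separation)) > 1e-12:
            raise ValueError("difference must equal measured - expected")

    @classmethod
    def from_measurement(
        cls, scan_id: str, measured: float, expected: float
    ) -> "WearRecord":
        return cls(
            scan_id=scan_id,
            measured_separation=float(measured),
            expected_separation=float(expected),
            difference=float(measured) - float(expected),
        )


@dataclass(frozen=True)
class SummaryStats:
    """Location/scale summary with a t-based confidence interval."""

    n: int
    mean: float
    median: float
    sd: float
    coefficient_of_variation: float  # percent
    ci_lower: float
    ci_upper: float
    confidence: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS of measured on expected separation (the 45-degree-line check)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_p: float
    intercept_p: float
    residual_sd: float
    f_value: float
    n: int


@dataclass(frozen=True)
class RepeatabilityResult:
    """ISO 5725-style repeatability of paired repeat measurements."""

    coefficient: float  # mm; bounds |trial1 - trial2| with ~95% probability
    within_pair_sd: float
    n_pairs: int
    difference_stats: SummaryStats  # of trial1 - trial2


def cup_head_separation(cup: SphereModel, head: SphereModel) -> float:
    """Distance in mm between the two fitted sphere centers (symmetric)."""
    return float(np.linalg.norm(cup.center - head.center))


def expected_separation(dx: float, dy: float, dz: float) -> float:
    """Expected separation from micrometer settings: the Euclidean norm."""
    v = np.array([dx, dy, dz], dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("displacements must be finite")
    return float(np.linalg.norm(v))


def summary_stats(values: Sequence[float], confidence: float = 0.99) -> SummaryStats:
    """Mean/median/SD/CV and a t confidence interval of the mean.

    CV is reported in percent (100*sd/mean; NaN when the mean is zero).
    Requires at least two values.
    """
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("summary statistics require at least 2 values")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = float("nan") if mean == 0 else 100.0 * sd / abs(mean)
    tq = float(scipy.stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tq * sd / np.sqrt(n)
    return SummaryStats(
        n=n,
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        coefficient_of_variation=cv,
        ci_lower=mean - half,
        ci_upper=mean + half,
        confidence=confidence,
    )


def wear_regression(records: Iterable[WearRecord]) -> RegressionResult:
    """OLS of measured on expected separation.

    For a perfect instrument the fit is the 45-degree line (slope 1,
    intercept 0). Requires at least three records and at least two
    distinct expected values.
    """
    recs = list(records)
    if len(recs) < 3:
        raise ValueError("regression requires at least 3 records")
    x = np.array([r.expected_separation for r in recs])
    y = np.array([r.measured_separation for r in recs])
    if np.unique(x).size < 2:
        raise ValueError("all expected separations are equal; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        slope_p=float(model.pvalues[1]),
        intercept_p=float(model.pvalues[0]),
        residual_sd=float(np.sqrt(model.mse_resid)),
        f_value=float(model.fvalue),
        n=len(recs),
    )


def repeatability(
    paired_measurements: Sequence[tuple[float, float]],
    confidence: float = 0.99,
) -> RepeatabilityResult:
    """Repeatability coefficient of paired repeat measurements.

    ``s_r^2 = sum(d_i^2) / (2 n)`` with ``d_i`` the within-pair
    differences, and the coefficient is ``2.77 * s_r``: the value below
    which the absolute difference of two repeats falls with ~95%
    probability. Also summarizes the signed differences themselves.
    """
    pairs = np.asarray(list(paired_measurements), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired_measurements must be (n, 2)")
    if len(pairs) < 2:
        raise ValueError("repeatability requires at least 2 pairs")
    d = pairs[:, 0] - pairs[:, 1]
    s_r = float(np.sqrt(np.sum(d**2) / (2.0 * len(d))))
    return RepeatabilityResult(
        coefficient=2.77 * s_r,
        within_pair_sd=s_r,
        n_pairs=len(d),
        difference_stats=summary_stats(d, confidence=confidence),
    )


def plot_measured_vs_expected(records: Iterable[WearRecord], path: str) -> None:
    """Scatter of measured vs expected separation with the 45-degree line
    and a ±0.1 mm agreement band; written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = list(records)
    x = np.array([r.expected_separation for r in recs])
    y = np.array([r.measured_separation for r in recs])
    lim = max(0.1, float(max(x.max(), y.max())) * 1.1)
    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.array([0.0, lim])
    ax.plot(grid, grid, "k-", lw=1, label="45° line")
    ax.plot(grid, grid + 0.1, "k--", lw=0.8, label="±0.1 mm")
    ax.plot(grid, grid - 0.1, "k--", lw=0.8)
    ax.plot(x, y, "o", ms=5)
    ax.set_xlabel("expected separation (mm)")
    ax.set_ylabel("measured separation (mm)")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
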