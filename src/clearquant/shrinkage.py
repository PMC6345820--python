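"""Organ-shrinkage analysis from calibrated 2D photographs.

Tissue clearing changes organ size and weight. The analysis photographs each
organ before and after clearing next to a 1-cm scale object, segments the
organ silhouette, converts its pixel area to cm² through the scale, and
normalises the after-area to the before-area (before = 100%). Weight is
recorded on a balance. Paired t-tests compare before vs after across
animals.

Stage order of the silhouette segmentation: median 3×3, fixed threshold,
opening, hole filling, dilation, hole filling, particle filtering (two-class
size split keeping the large class), largest component. The scale object's
region of interest is excluded from organ candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import core
from .core import BinaryMask, Image2D, StructuringElement
from .errors import (
    CalibrationError,
    InvalidParameterError,
    SegmentationError,
)

__all__ = [
    "ScaleCalibration",
    "OrganSegConfig",
    "ShrinkageRecord",
    "PairedTestResult",
    "to_grayscale",
    "calibrate_scale",
    "segment_organ",
    "measure_area",
    "normalize_pair",
    "paired_t_test",
    "measure_organ_pair",
    "run_study",
    "plot_study",
]

# ITU-R 709 luminance weights, as used by standard RGB->gray conversions
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel size derived from a scale object of known physical length."""

    pixels_per_cm: float
    ruler_pixel_count: int
    ruler_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pixels_per_cm > 0 and np.isfinite(self.pixels_per_cm)):
            raise InvalidParameterError("pixels_per_cm must be positive")


@dataclass(frozen=True)
class OrganSegConfig:
    """Silhouette segmentation parameters.

    ``threshold=None`` uses the photo's post-median mid-range value.
    ``dilation_radius`` may be 0 to skip the dilation stage (dilation biases
    area upward; see the area-accuracy notes in the docs).
    """

    median_window: int = 3
    threshold: float | None = None
    opening_radius: int = 1
    dilation_radius: int = 1
    particle_filter: bool = True
    connectivity: int = 8


@dataclass(frozen=True)
class ShrinkageRecord:
    """Per-organ before/after measurements; area normalised to before=100%."""

    organ: str
    weight_before_g: float
    weight_after_g: float
    area_before_cm2: float
    area_after_cm2: float

    @property
    def area_after_pct(self) -> float:
        return normalize_pair(self.area_before_cm2, self.area_after_cm2)

    @property
    def weight_delta_g(self) -> float:
        return self.weight_after_g - self.weight_before_g


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test at significance level 0.05."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def to_grayscale(photo: Image2D | np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale; identity for single-channel input."""
    values = photo.values if isinstance(photo, Image2D) else np.asarray(photo, float)
    if values.ndim == 2:
        return values
    return values[..., :3] @ _LUMA


def _roi_slices(roi: Sequence[int], shape: tuple[int, ...]) -> tuple[slice, slice]:
    y0, y1, x0, x1 = (int(v) for v in roi)
    if not (0 <= y0 < y1 <= shape[0] and 0 <= x0 < x1 <= shape[1]):
        raise InvalidParameterError(f"ROI {roi!r} outside image of shape {shape}")
    return slice(y0, y1), slice(x0, x1)


def calibrate_scale(
    photo: Image2D | np.ndarray,
    ruler_roi: Sequence[int],
    ruler_length_cm: float = 1.0,
) -> ScaleCalibration:
    """Count the scale object's pixel extent and convert to pixels per cm.

    ``ruler_roi`` is ``(row_start, row_stop, col_start, col_stop)``. The
    region is thresholded (Otsu), the largest component taken as the scale
    object, and its longest bounding-box axis divided by the known length.
    """
    gray = to_grayscale(photo)
    ys, xs = _roi_slices(ruler_roi, gray.shape)
    sub = gray[ys, xs]
    if sub.size == 0:
        raise CalibrationError("empty ruler ROI")
    if sub.max() == sub.min():
        raise CalibrationError("ruler ROI is constant: no scale object found")
    t = core.otsu_threshold(sub)
    mask = core.apply_threshold(sub, t, ">")
    labels = core.connected_components(mask, connectivity=8)
    if labels.n_objects == 0:
        raise CalibrationError("no object found in ruler ROI")
    biggest = core.largest_component(labels).values
    rows = np.flatnonzero(biggest.any(axis=1))
    cols = np.flatnonzero(biggest.any(axis=0))
    extent = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    return ScaleCalibration(
        pixels_per_cm=extent / float(ruler_length_cm),
        ruler_pixel_count=int(biggest.sum()),
        ruler_length_cm=float(ruler_length_cm),
    )


def _particle_filter(labels: core.LabelMap) -> BinaryMask:
    """Two-class split of component sizes (Otsu on the size values), keeping
    the large class. Fewer than three components, or components of uniform
    size, pass through unchanged."""
    counts = np.bincount(labels.labels.ravel(), minlength=labels.n_objects + 1)[1:]
    if labels.n_objects < 3 or counts.min() == counts.max():
        return BinaryMask(labels.labels > 0)
    t = core.otsu_threshold(counts.astype(np.float64))
    keep = np.concatenate(([False], counts > t))
    return BinaryMask(keep[labels.labels])


def segment_organ(
    photo: Image2D | np.ndarray,
    config: OrganSegConfig | None = None,
    ruler_roi: Sequence[int] | None = None,
) -> BinaryMask:
    """Segment the organ silhouette as the biggest binary object.

    Stage order: median 3×3 → fixed threshold → opening → hole fill →
    dilation → hole fill → particle filter → largest component. Pixels
    inside ``ruler_roi`` are removed from the candidate foreground so the
    scale object can never be picked as the organ.
    """
    config = config or OrganSegConfig()
    gray = to_grayscale(photo)
    smoothed = core.median_filter(gray, config.median_window)
    if config.threshold is None:
        t = (float(smoothed.min()) + float(smoothed.max())) / 2.0
    else:
        t = float(config.threshold)
    mask = core.apply_threshold(smoothed, t, ">=")
    work = mask.values.copy()
    if ruler_roi is not None:
        ys, xs = _roi_slices(ruler_roi, work.shape)
        work[ys, xs] = False
    mask = BinaryMask(work)
    if not work.any():
        raise SegmentationError("threshold produced an empty mask")
    if config.opening_radius > 0:
        mask = core.binary_morphology(
            mask, "open", StructuringElement("disk", config.opening_radius)
        )
    mask = core.binary_morphology(mask, "fill_holes")
    if config.dilation_radius > 0:
        mask = core.binary_morphology(
            mask, "dilate", StructuringElement("disk", config.dilation_radius)
        )
        mask = core.binary_morphology(mask, "fill_holes")
    labels = core.connected_components(mask, config.connectivity)
    if labels.n_objects == 0:
        raise SegmentationError("no organ candidate left after morphology")
    if config.particle_filter:
        mask = _particle_filter(labels)
        labels = core.connected_components(mask, config.connectivity)
        if labels.n_objects == 0:
            raise SegmentationError("particle filter removed all candidates")
    return core.largest_component(labels)


def measure_area(mask: BinaryMask, calib: ScaleCalibration) -> float:
    """Area in cm²: foreground pixel count divided by (pixels per cm)²."""
    return float(np.count_nonzero(mask.values)) / calib.pixels_per_cm**2


def normalize_pair(before: float, after: float) -> float:
    """After-measurement as a percentage of the before-measurement."""
    if not before > 0:
        raise InvalidParameterError("before-value must be > 0")
    return 100.0 * after / before


def paired_t_test(
    before: Sequence[float], after: Sequence[float]
) -> PairedTestResult:
    """Two-sided paired t-test on differences ``after - before``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``n-1`` degrees of freedom.
    Identical pairs give ``t=0, p=1``; nonzero differences with zero
    variance give an infinite t with ``p=0`` (documented convention).
    """
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.shape != a.shape or b.ndim != 1:
        raise InvalidParameterError("before/after must be equal-length 1D sequences")
    n = b.size
    if n < 2:
        raise InvalidParameterError("paired t-test requires n >= 2")
    d = a - b
    df = n - 1
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, df, 1.0)
        return PairedTestResult(float(np.sign(mean)) * np.inf, df, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sstats.t.sf(abs(t), df))
    return PairedTestResult(float(t), df, min(p, 1.0))


def measure_organ_pair(
    organ: str,
    photo_before: Image2D | np.ndarray,
    roi_before: Sequence[int],
    photo_after: Image2D | np.ndarray,
    roi_after: Sequence[int],
    weight_before_g: float,
    weight_after_g: float,
    config: OrganSegConfig | None = None,
) -> ShrinkageRecord:
    """Calibrate, segment and measure one organ's before/after photo pair."""
    calib_b = calibrate_scale(photo_before, roi_before)
    calib_a = calibrate_scale(photo_after, roi_after)
    mask_b = segment_organ(photo_before, config, ruler_roi=roi_before)
    mask_a = segment_organ(photo_after, config, ruler_roi=roi_after)
    return ShrinkageRecord(
        organ=organ,
        weight_before_g=float(weight_before_g),
        weight_after_g=float(weight_after_g),
        area_before_cm2=measure_area(mask_b, calib_b),
        area_after_cm2=measure_area(mask_a, calib_a),
    )


def run_study(
    records: Sequence[ShrinkageRecord],
) -> tuple[pd.DataFrame, dict[str, PairedTestResult]]:
    """Tabulate per-organ records and test area and weight before vs after."""
    if not records:
        raise InvalidParameterError("no shrinkage records")
    table = pd.DataFrame(
        {
            "organ": [r.organ for r in records],
            "weight_before_g": [r.weight_before_g for r in records],
            "weight_after_g": [r.weight_after_g for r in records],
            "weight_delta_g": [r.weight_delta_g for r in records],
            "area_before_cm2": [r.area_before_cm2 for r in records],
            "area_after_cm2": [r.area_after_cm2 for r in records],
            "area_after_pct": [r.area_after_pct for r in records],
        }
    )
    tests: dict[str, PairedTestResult] = {}
    if len(records) >= 2:
        tests["area"] = paired_t_test(
            table["area_before_cm2"], table["area_after_cm2"]
        )
        tests["weight"] = paired_t_test(
            table["weight_before_g"], table["weight_after_g"]
        )
    return table, tests


def plot_study(table: pd.DataFrame, path) -> None:
    """Bar plot: areas as % of before (before fixed at 100%) and weights (g)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_area, ax_weight) = plt.subplots(1, 2, figsize=(11, 4.5))
    x = np.arange(len(table))
    w = 0.38
    ax_area.bar(x - w / 2, np.full(len(table), 100.0), w, label="before", color="#888")
    ax_area.bar(x + w / 2, table["area_after_pct"], w, label="after", color="#c0392b")
    ax_area.set_ylabel("area (% of before)")
    ax_area.axhline(100.0, lw=0.6, color="k")
    ax_weight.bar(x - w / 2, table["weight_before_g"], w, label="before", color="#888")
    ax_weight.bar(x + w / 2, table["weight_after_g"], w, label="after", color="#2c3e50")
    ax_weight.set_ylabel("weight (g)")
    for ax in (ax_area, ax_weight):
        ax.set_xticks(x)
        ax.set_xticklabels(table["organ"], rotation=45, ha="right")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
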