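"""Image-processing primitives shared by every pipeline.

Conventions used throughout the package:

* 3D grids are indexed ``(z, y, x)``, 0-based; 2D grids ``(y, x)``.
* Physical calibration is carried as voxel (or pixel) edge lengths in
  micrometres, ordered like the axes.
* Binary masks are boolean arrays of the same shape as their source image.
* Label maps use 0 for background and consecutive positive integers
  ``1..n_objects`` assigned in raster-scan order of first encounter, so a
  given mask always labels the same way on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball, cube, disk, square

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    NoObjectError,
)

__all__ = [
    "ImageStack3D",
    "Image2D",
    "BinaryMask",
    "LabelMap",
    "StructuringElement",
    "ObjectRecord",
    "median_filter",
    "otsu_threshold",
    "apply_threshold",
    "binary_morphology",
    "connected_components",
    "largest_component",
    "extract_features",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageStack3D:
    """One-channel 3D intensity grid with anisotropic voxel dimensions.

    Parameters
    ----------
    values
        Non-negative intensities, shape ``(nz, ny, nx)``.
    voxel_size
        Physical voxel edge lengths ``(dz, dy, dx)`` in micrometres.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise InvalidParameterError(
                f"stack must be 3D (z, y, x); got {values.ndim}D"
            )
        if min(values.shape) < 1:
            raise InvalidParameterError("stack must have >= 1 voxel per axis")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("stack intensities must be finite")
        if values.min() < 0:
            raise InvalidParameterError("stack intensities must be >= 0")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 or not np.isfinite(v) for v in vs):
            raise InvalidParameterError(
                f"voxel_size must be three positive lengths (dz, dy, dx); got {self.voxel_size!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass(frozen=True)
class Image2D:
    """2D intensity or RGB image, indexed ``(y, x)`` (RGB: trailing axis 3)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim == 3 and values.shape[-1] not in (3, 4):
            raise InvalidParameterError("3D input to Image2D must be RGB(A)")
        if values.ndim not in (2, 3):
            raise InvalidParameterError("Image2D expects (y, x) or (y, x, c)")
        if min(values.shape[:2]) < 1:
            raise InvalidParameterError("image must have >= 1 pixel per axis")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("image values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask with the same shape as its source grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != bool:
            raise InvalidParameterError("BinaryMask requires a boolean array")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class LabelMap:
    """Integer object labels over a grid; 0 is background.

    Positive labels are exactly ``1..n_objects`` with no gaps, assigned in
    raster-scan order of first encounter.
    """

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise InvalidParameterError("labels must be integers")
        if labels.size and labels.min() < 0:
            raise InvalidParameterError("labels must be non-negative")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class StructuringElement:
    """Centered symmetric footprint for binary morphology.

    ``ball``/``cube`` are 3D, ``disk``/``square`` 2D; ``radius`` is counted
    in voxels/pixels, so a radius-1 ball spans 3 voxels per axis.
    """

    shape: Literal["ball", "disk", "cube", "square"]
    radius: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("ball", "disk", "cube", "square"):
            raise InvalidParameterError(f"unknown footprint shape {self.shape!r}")
        if int(self.radius) < 1:
            raise InvalidParameterError("footprint radius must be >= 1")
        object.__setattr__(self, "radius", int(self.radius))

    @property
    def ndim(self) -> int:
        return 3 if self.shape in ("ball", "cube") else 2

    def footprint(self) -> np.ndarray:
        r = self.radius
        if self.shape == "ball":
            return ball(r).astype(bool)
        if self.shape == "disk":
            return disk(r).astype(bool)
        if self.shape == "cube":
            return cube(2 * r + 1).astype(bool)
        return square(2 * r + 1).astype(bool)


@dataclass(frozen=True)
class ObjectRecord:
    """Per-object geometry and intensity features.

    ``volume_um3`` holds physical volume (µm³) for 3D objects and physical
    area (µm² or cm², whatever the caller's pixel units imply) for 2D ones.
    ``centroid_um`` is the unweighted mean of voxel coordinates scaled by the
    voxel size (physical µm, 0-based origin). ``bbox`` is a per-axis tuple of
    half-open index ranges ``(start, stop)``. ``object_class`` is 1 for
    accepted glomeruli, 2 for background / partially visible objects, and
    ``None`` before classification.
    """

    label: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, ...]
    bbox: tuple[tuple[int, int], ...]
    border_touch: bool
    mean_intensity: float
    object_class: int | None = None

    def with_class(self, object_class: int) -> "ObjectRecord":
        if object_class not in (1, 2):
            raise InvalidParameterError("object_class must be 1 or 2")
        return replace(self, object_class=object_class)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _unwrap(image) -> np.ndarray:
    if isinstance(image, (ImageStack3D, Image2D, BinaryMask)):
        return image.values
    if isinstance(image, LabelMap):
        return image.labels
    return np.asarray(image)


def _rewrap(image, values: np.ndarray):
    if isinstance(image, ImageStack3D):
        return ImageStack3D(values, image.voxel_size)
    if isinstance(image, Image2D):
        return Image2D(values)
    if isinstance(image, BinaryMask):
        return BinaryMask(values)
    return values


_CONNECTIVITY_RANK = {
    (2, 4): 1,
    (2, 8): 2,
    (3, 6): 1,
    (3, 18): 2,
    (3, 26): 3,
}


def connectivity_structure(ndim: int, connectivity: int) -> np.ndarray:
    """Adjacency footprint for a neighbour count (4/8 in 2D, 6/18/26 in 3D)."""
    try:
        rank = _CONNECTIVITY_RANK[(ndim, connectivity)]
    except KeyError:
        raise InvalidParameterError(
            f"connectivity {connectivity} invalid for {ndim}D "
            "(use 4/8 in 2D, 6/18/26 in 3D)"
        ) from None
    return ndi.generate_binary_structure(ndim, rank)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def median_filter(image, window: int | Sequence[int] = 3):
    """Median filter with edge replication at the borders.

    ``window`` is an odd side length, scalar or per-axis. Edge replication
    (rather than zero padding) avoids the spurious dark rim that would bias a
    subsequent histogram threshold.
    """
    values = _unwrap(image)
    if np.isscalar(window):
        sizes = (int(window),) * values.ndim
    else:
        sizes = tuple(int(w) for w in window)
    if len(sizes) != values.ndim:
        raise InvalidParameterError(
            f"window has {len(sizes)} sides for a {values.ndim}D image"
        )
    for w in sizes:
        if w < 1 or w % 2 == 0:
            raise InvalidParameterError(f"window sides must be odd and >= 1, got {w}")
    out = ndi.median_filter(values, size=sizes, mode="nearest")
    return _rewrap(image, out)


def otsu_threshold(image, n_bins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance on a binned histogram.

    The histogram uses ``n_bins`` equal-width bins spanning ``[min, max]`` of
    the data; the returned threshold is the center of the last bin of the low
    class (argmax of the between-class variance; first bin wins ties), so
    binarising with ``> t`` or ``>= next bin edge`` separates the classes.

    Raises
    ------
    DegenerateInputError
        If the image is constant (no two classes to separate).
    """
    values = _unwrap(image)
    flat = np.asarray(values, dtype=np.float64).ravel()
    if int(n_bins) < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    hist, edges = np.histogram(flat, bins=int(n_bins), range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(np.float64)

    w0 = np.cumsum(hist)                      # class weights for split after bin i
    w1 = w0[-1] - w0
    m = np.cumsum(hist * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = between[:-1]                    # a split must leave both classes nonempty
    between[~np.isfinite(between)] = -np.inf
    idx = int(np.argmax(between))             # first maximum on ties
    return float(centers[idx])


def apply_threshold(image, t: float, mode: Literal[">=", ">"] = ">=") -> BinaryMask:
    """Binarise an image against a fixed threshold."""
    if not np.isfinite(t):
        raise InvalidParameterError("threshold must be finite")
    values = _unwrap(image)
    if mode == ">=":
        out = values >= t
    elif mode == ">":
        out = values > t
    else:
        raise InvalidParameterError(f"mode must be '>=' or '>', got {mode!r}")
    return BinaryMask(out)


def binary_morphology(
    mask,
    op: Literal["erode", "dilate", "open", "close", "fill_holes"],
    se: StructuringElement | None = None,
) -> BinaryMask:
    """Set-theoretic binary morphology with an out-of-grid background.

    ``fill_holes`` sets to foreground every background component that is not
    connected to the grid border (background connectivity is the minimal
    face-adjacency); it takes no footprint.
    """
    values = _unwrap(mask)
    if values.dtype != bool:
        values = values.astype(bool)
    if op == "fill_holes":
        return BinaryMask(ndi.binary_fill_holes(values))
    if se is None:
        se = StructuringElement("ball" if values.ndim == 3 else "disk", 1)
    if se.ndim != values.ndim:
        raise InvalidParameterError(
            f"{se.shape!r} footprint is {se.ndim}D but mask is {values.ndim}D"
        )
    fp = se.footprint()
    if op == "erode":
        out = ndi.binary_erosion(values, structure=fp, border_value=0)
    elif op == "dilate":
        out = ndi.binary_dilation(values, structure=fp, border_value=0)
    elif op == "open":
        out = ndi.binary_opening(values, structure=fp)
    elif op == "close":
        # pad by the footprint radius so closing matches the infinite-domain
        # definition (and stays extensive) at the grid border
        pad = [(s // 2, s // 2) for s in fp.shape]
        padded = np.pad(values, pad, mode="constant", constant_values=False)
        closed = ndi.binary_closing(padded, structure=fp)
        out = closed[tuple(slice(p0, s + p0) for (p0, _), s in zip(pad, values.shape))]
    else:
        raise InvalidParameterError(f"unknown morphology op {op!r}")
    return BinaryMask(out)


def connected_components(mask, connectivity: int | None = None) -> LabelMap:
    """Label connected foreground components.

    Labels ``1..K`` follow raster-scan order of first encounter, so the
    output is reproducible across runs and platforms. Default connectivity is
    8 in 2D and 26 in 3D (maximal: keeps a blurred shell as one object).
    """
    values = _unwrap(mask)
    if values.dtype != bool:
        values = values.astype(bool)
    if connectivity is None:
        connectivity = 8 if values.ndim == 2 else 26
    structure = connectivity_structure(values.ndim, connectivity)
    raw, n = ndi.label(values, structure=structure)
    if n > 1:
        flat = raw.ravel()
        uniq, first = np.unique(flat, return_index=True)
        keep = uniq > 0
        order = np.argsort(first[keep], kind="stable")
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[uniq[keep][order]] = np.arange(1, n + 1)
        raw = remap[raw]
    return LabelMap(raw, n)


def largest_component(labels: LabelMap) -> BinaryMask:
    """Mask of the object with the most voxels; ties go to the smaller label.

    Because labels follow raster-scan first encounter, the tie-break selects
    the object first encountered in raster order.
    """
    if labels.n_objects < 1:
        raise NoObjectError("label map contains no objects")
    counts = np.bincount(labels.labels.ravel(), minlength=labels.n_objects + 1)
    best = int(np.argmax(counts[1:])) + 1     # argmax returns first maximum
    return BinaryMask(labels.labels == best)


def _border_labels(labels: np.ndarray) -> set[int]:
    found: set[int] = set()
    for axis in range(labels.ndim):
        for face in (0, -1):
            sl = [slice(None)] * labels.ndim
            sl[axis] = face
            found.update(np.unique(labels[tuple(sl)]).tolist())
    found.discard(0)
    return found


def extract_features(
    labels: LabelMap,
    image,
    voxel_size: Sequence[float],
) -> list[ObjectRecord]:
    """Per-object features: size, physical volume/area, centroid, bbox,
    border-touch flag and mean intensity.

    ``volume_um3`` is ``voxel_count × prod(voxel_size)``; centroids are the
    unweighted mean of voxel indices scaled to physical coordinates.
    """
    lab = labels.labels
    values = _unwrap(image)
    if values.shape != lab.shape:
        raise InvalidParameterError(
            f"image shape {values.shape} != label shape {lab.shape}"
        )
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != lab.ndim or any(v <= 0 for v in vs):
        raise InvalidParameterError(
            f"voxel_size must give one positive length per axis; got {voxel_size!r}"
        )
    n = labels.n_objects
    if n == 0:
        return []

    flat = lab.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    element_volume = float(np.prod(vs))
    intensity_sums = np.bincount(flat, weights=values.ravel(), minlength=n + 1)[1:]

    coord_means = []
    for axis in range(lab.ndim):
        idx = np.arange(lab.shape[axis], dtype=np.float64)
        axis_coord = idx.reshape(
            [-1 if a == axis else 1 for a in range(lab.ndim)]
        )
        sums = np.bincount(
            flat, weights=np.broadcast_to(axis_coord, lab.shape).ravel(),
            minlength=n + 1,
        )[1:]
        coord_means.append(sums / counts)

    slices = ndi.find_objects(lab, max_label=n)
    on_border = _border_labels(lab)

    records = []
    for i in range(n):
        sl = slices[i]
        bbox = tuple((s.start, s.stop) for s in sl)
        centroid = tuple(coord_means[a][i] * vs[a] for a in range(lab.ndim))
        records.append(
            ObjectRecord(
                label=i + 1,
                voxel_count=int(counts[i]),
                volume_um3=float(counts[i]) * element_volume,
                centroid_um=centroid,
                bbox=bbox,
                border_touch=(i + 1) in on_border,
                mean_intensity=float(intensity_sums[i] / counts[i]),
            )
        )
    return records
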