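"""Readers and writers for stacks, masks, label maps and object tables.

TIFF is the interchange format for volumetric data (one page per z-slice);
voxel sizes travel either in the call or in ImageJ-style TIFF metadata
(``XResolution``/``YResolution`` plus the ``spacing`` field). Proprietary
microscope containers are not parsed — export to TIFF first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import BinaryMask, Image2D, ImageStack3D, LabelMap, ObjectRecord
from .errors import InvalidParameterError, StackReadError

__all__ = [
    "read_stack",
    "write_stack",
    "read_photo",
    "write_photo",
    "write_labelmap",
    "read_labelmap",
    "write_mask",
    "write_object_table",
    "read_object_table",
    "write_json",
]

MAX_LABELS_16BIT = 65535


def write_stack(path, stack: ImageStack3D) -> None:
    """Write a stack as multi-page float32 TIFF with voxel-size metadata."""
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.values.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def _voxel_size_from_tags(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata or {}
    spacing = meta.get("spacing")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if spacing is None or xres is None or yres is None:
        return None
    xr = xres.value[0] / xres.value[1]
    yr = yres.value[0] / yres.value[1]
    if xr <= 0 or yr <= 0 or spacing <= 0:
        return None
    return (float(spacing), 1.0 / yr, 1.0 / xr)


def read_stack(path, voxel_size: Sequence[float] | None = None) -> ImageStack3D:
    """Read a single-channel multi-page TIFF as an :class:`ImageStack3D`.

    ``voxel_size`` (dz, dy, dx in µm) overrides file metadata; if neither is
    available the read fails rather than assuming a silent default.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            values = tif.asarray()
            tag_size = _voxel_size_from_tags(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackReadError(f"cannot read TIFF stack {path}: {exc}") from exc
    if values.ndim == 2:
        values = values[None, ...]
    if values.ndim != 3:
        raise StackReadError(
            f"{path}: expected a single-channel z-stack, got shape {values.shape}; "
            "select/export one channel first"
        )
    size = tuple(voxel_size) if voxel_size is not None else tag_size
    if size is None:
        raise StackReadError(
            f"{path}: no voxel size in TIFF metadata and none supplied; "
            "pass voxel_size=(dz, dy, dx) in um"
        )
    return ImageStack3D(values.astype(np.float64), tuple(float(v) for v in size))


def read_photo(path) -> Image2D:
    """Read a PNG/JPEG/TIFF photograph (grayscale or RGB)."""
    return Image2D(np.asarray(iio.imread(str(path)), dtype=np.float64))


def write_photo(path, image: Image2D) -> None:
    values = np.clip(image.values, 0, 255).astype(np.uint8)
    iio.imwrite(str(path), values)


def write_labelmap(path, labels: LabelMap) -> None:
    """Write a label map as 16-bit TIFF (at most 65,535 objects)."""
    if labels.n_objects > MAX_LABELS_16BIT:
        raise InvalidParameterError(
            f"{labels.n_objects} objects exceed the 16-bit label limit"
        )
    tifffile.imwrite(str(path), labels.labels.astype(np.uint16))


def read_labelmap(path) -> LabelMap:
    values = tifffile.imread(str(path)).astype(np.int32)
    return LabelMap(values, int(values.max()))


def write_mask(path, mask: BinaryMask) -> None:
    """Write a binary mask as 8-bit TIFF (255 = foreground)."""
    tifffile.imwrite(str(path), (mask.values.astype(np.uint8)) * 255)


_TABLE_COLUMNS = [
    "label", "voxel_count", "volume_um3", "centroid_um", "bbox",
    "border_touch", "mean_intensity", "object_class",
]


def write_object_table(path, records: Sequence[ObjectRecord]) -> None:
    """Write object records as CSV with fixed, documented columns."""
    rows = [
        {
            "label": r.label,
            "voxel_count": r.voxel_count,
            "volume_um3": r.volume_um3,
            "centroid_um": json.dumps(list(r.centroid_um)),
            "bbox": json.dumps([list(b) for b in r.bbox]),
            "border_touch": r.border_touch,
            "mean_intensity": r.mean_intensity,
            "object_class": "" if r.object_class is None else r.object_class,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def read_object_table(path) -> list[ObjectRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        cls = row["object_class"]
        records.append(
            ObjectRecord(
                label=int(row["label"]),
                voxel_count=int(row["voxel_count"]),
                volume_um3=float(row["volume_um3"]),
                centroid_um=tuple(json.loads(row["centroid_um"])),
                bbox=tuple(tuple(b) for b in json.loads(row["bbox"])),
                border_touch=bool(row["border_touch"]),
                mean_intensity=float(row["mean_intensity"]),
                object_class=None if pd.isna(cls) else int(cls),
            )
        )
    return records


def write_json(path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
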