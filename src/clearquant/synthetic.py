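"""Ground-truthed synthetic scenes emulating cleared-organ acquisitions.

Two generators cover the package's input domains:

* :func:`generate_kidney_stack` builds a 3D cleared-kidney volume: bright
  glomerular shells (basement-membrane staining, with a dimmer stained
  capillary tuft inside), dye-filled vessel tubes crossing the volume, small
  bright background objects (tubule debris / aggregates), anisotropic
  axial-dominant Gaussian blur, and Poisson–Gaussian noise. With a large
  cationic dye the tubule background stays low ("PEI regime"); the smaller
  conjugate leaks into tubules and raises it ("PEI-S regime",
  :meth:`KidneySceneSpec.pei_s`).
* :func:`generate_organ_photo_pair` builds before/after organ photographs:
  a smooth irregular blob, a 1-cm ruler bar of known pixel length, a flash
  illumination gradient and sensor noise; the after-photo scales the organ
  contour by a linear shrink factor about its centroid.

Every generator is a pure function of its spec (which embeds the seed), and
the returned truth tables are sufficient to score each downstream pipeline
without re-inspecting the images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import Image2D, ImageStack3D
from .errors import InvalidParameterError, PlacementError

__all__ = [
    "KidneySceneSpec",
    "KidneyTruth",
    "OrganPhotoSpec",
    "PhotoTruth",
    "generate_kidney_stack",
    "generate_vessel_stack",
    "generate_organ_photo_pair",
]


# ---------------------------------------------------------------------------
# 3D kidney / vessel scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KidneySceneSpec:
    """Parameters of a synthetic cleared-kidney volume.

    Defaults describe a 128³ voxel crop at 5 µm isotropic sampling
    (640 µm cube, ≈150 glomeruli/mm³ — cortical density of an adult mouse),
    glomerular radii 36 ± 3 µm truncated to [30, 44] µm so the mean
    digitized volume is ≈2×10⁵ µm³, a 10 µm stained shell over a dimmer
    tuft, low tubule background, and light-sheet-like blur (axial σ 5 µm,
    lateral 2 µm). ``n_border_truncated`` glomeruli are planted clipped by
    the volume border, emulating partially visible objects.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: tuple[float, float, float] = (5.0, 5.0, 5.0)
    n_glomeruli: int = 43
    n_border_truncated: int = 3
    radius_mean_um: float = 36.0
    radius_sd_um: float = 3.0
    radius_clip_um: tuple[float, float] = (30.0, 44.0)
    shell_thickness_um: float = 10.0
    n_background_objects: int = 12
    background_radius_um: tuple[float, float] = (10.0, 16.0)
    n_vessels: int = 3
    vessel_radius_um: float = 15.0
    foreground_intensity: float = 200.0
    interior_intensity: float = 120.0
    tubule_intensity: float = 10.0
    blur_sigma_um: tuple[float, float, float] = (5.0, 2.0, 2.0)
    poisson_gain: float = 1.0
    gaussian_sd: float = 2.0
    min_gap_um: float = 45.0
    max_attempts: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_border_truncated > self.n_glomeruli:
            raise InvalidParameterError(
                "n_border_truncated cannot exceed n_glomeruli"
            )
        if self.radius_clip_um[0] <= 0 or self.radius_clip_um[1] < self.radius_clip_um[0]:
            raise InvalidParameterError("radius_clip_um must be ascending positives")
        if min(self.foreground_intensity, self.interior_intensity,
               self.tubule_intensity) < 0:
            raise InvalidParameterError("intensities must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel_size must be positive")

    @classmethod
    def pei_s(cls, **overrides) -> "KidneySceneSpec":
        """High-tubule-background variant (small-conjugate leakage)."""
        overrides.setdefault("tubule_intensity", 80.0)
        return cls(**overrides)


@dataclass(frozen=True)
class KidneyTruth:
    """Planted ground truth for a kidney scene.

    ``table`` has one row per planted object (glomerulus or background
    blob): center (µm), radius (µm), digitized voxel count and volume, and
    the border-truncated flag. ``glomerulus_labels`` is a label map of the
    digitized glomerulus voxel sets (ids = ``object_id``);
    ``vessel_mask`` marks the planted tube voxels.
    """

    table: pd.DataFrame
    glomerulus_labels: np.ndarray
    vessel_mask: np.ndarray

    def interior_glomeruli(self) -> pd.DataFrame:
        t = self.table
        return t[(t["kind"] == "glomerulus") & ~t["border_truncated"]]


def _ball_patch(shape, center, radius_vox_per_axis):
    """Index grid and scaled distance for a local patch around a sphere."""
    lo = np.maximum(0, np.floor(center - radius_vox_per_axis - 2)).astype(int)
    hi = np.minimum(shape, np.ceil(center + radius_vox_per_axis + 3)).astype(int)
    if np.any(hi <= lo):
        return None, None, None
    axes = [np.arange(lo[a], hi[a], dtype=np.float64) for a in range(3)]
    grids = np.meshgrid(*axes, indexing="ij")
    return lo, hi, grids


def _sphere_distance_um(grids, center, voxel_size):
    d2 = np.zeros_like(grids[0])
    for a in range(3):
        d2 += ((grids[a] - center[a]) * voxel_size[a]) ** 2
    return np.sqrt(d2)


def _vessel_paths(rng: np.random.Generator, shape, n_vessels: int):
    """Centerlines as dense point chains: quadratic Béziers from face to
    face; tubes after the first may branch off an earlier one."""
    dims = np.array(shape, dtype=np.float64) - 1.0
    paths: list[np.ndarray] = []

    def face_point():
        axis = rng.integers(3)
        p = rng.uniform(0, dims)
        p[axis] = 0.0 if rng.integers(2) == 0 else dims[axis]
        return p

    for i in range(n_vessels):
        if i > 0 and rng.random() < 0.5:
            parent = paths[rng.integers(len(paths))]
            p0 = parent[rng.integers(len(parent))].copy()
        else:
            p0 = face_point()
        p2 = face_point()
        p1 = rng.uniform(0.2 * dims, 0.8 * dims)
        length = np.linalg.norm(p2 - p0) + 1.0
        t = np.linspace(0.0, 1.0, max(8, int(3 * length)))[:, None]
        curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        paths.append(curve)
    return paths


def _stamp_tube(mask: np.ndarray, path: np.ndarray, radius_vox_per_axis):
    shape = np.array(mask.shape)
    r = radius_vox_per_axis
    for p in path:
        lo = np.maximum(0, np.floor(p - r - 1)).astype(int)
        hi = np.minimum(shape, np.ceil(p + r + 2)).astype(int)
        if np.any(hi <= lo):
            continue
        axes = [np.arange(lo[a], hi[a], dtype=np.float64) for a in range(3)]
        grids = np.meshgrid(*axes, indexing="ij")
        d2 = sum(((grids[a] - p[a]) / r[a]) ** 2 for a in range(3))
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= 1.0


def generate_kidney_stack(
    spec: KidneySceneSpec,
) -> tuple[ImageStack3D, KidneyTruth]:
    """Render a kidney scene and its ground truth.

    Placement is rejection sampling: vessels first, then border-truncated
    glomeruli, interior glomeruli, and background blobs, each keeping a
    physical surface gap of ``min_gap_um`` to everything placed before it.
    Rendering order: intensities → Gaussian blur → Poisson + Gaussian noise.

    Raises
    ------
    PlacementError
        If an object cannot be placed within ``max_attempts`` draws
        (infeasible packing for the requested counts and radii).
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape, dtype=int)
    vs = np.array(spec.voxel_size, dtype=np.float64)

    vessel_mask = np.zeros(tuple(shape), dtype=bool)
    vessel_paths = _vessel_paths(rng, spec.shape, spec.n_vessels)
    vessel_samples = (
        np.concatenate(vessel_paths) if vessel_paths else np.empty((0, 3))
    )
    rvessel_vox = spec.vessel_radius_um / vs
    for path in vessel_paths:
        _stamp_tube(vessel_mask, path, rvessel_vox)

    centers_um: list[np.ndarray] = []
    radii_um: list[float] = []

    def clearance_ok(center_vox: np.ndarray, radius_um: float) -> bool:
        c_um = center_vox * vs
        for cj, rj in zip(centers_um, radii_um):
            if np.linalg.norm(c_um - cj) < radius_um + rj + spec.min_gap_um:
                return False
        if len(vessel_samples):
            d = np.linalg.norm((vessel_samples - center_vox) * vs, axis=1)
            if d.min() < radius_um + spec.vessel_radius_um + spec.min_gap_um:
                return False
        return True

    def place(radius_um: float, border: bool) -> np.ndarray:
        r_vox = radius_um / vs
        lo = r_vox + 4.0
        hi = shape - 1.0 - r_vox - 4.0
        if np.any(hi <= lo):
            raise PlacementError("object radius too large for the grid")
        for _ in range(spec.max_attempts):
            c = rng.uniform(lo, hi)
            if border:
                axis = int(rng.integers(3))
                side = int(rng.integers(2))
                # center just outside the grid: roughly a third of the
                # sphere remains visible, like a glomerulus cut by the crop
                off = 0.2 * r_vox[axis]
                c[axis] = -off if side == 0 else shape[axis] - 1 + off
            if clearance_ok(c, radius_um):
                centers_um.append(c * vs)
                radii_um.append(radius_um)
                return c
        raise PlacementError(
            f"could not place object of radius {radius_um:.1f} um after "
            f"{spec.max_attempts} attempts"
        )

    image = np.full(tuple(shape), float(spec.tubule_intensity))
    image[vessel_mask] = spec.foreground_intensity
    glom_labels = np.zeros(tuple(shape), dtype=np.int32)
    rows = []
    voxel_volume = float(np.prod(vs))

    # truncated-normal radii: resample out-of-range draws so no atom of
    # identical radii accumulates at the truncation bounds
    glom_radii = rng.normal(spec.radius_mean_um, spec.radius_sd_um, spec.n_glomeruli)
    lo_r, hi_r = spec.radius_clip_um
    for _ in range(100):
        bad = (glom_radii < lo_r) | (glom_radii > hi_r)
        if not bad.any():
            break
        glom_radii[bad] = rng.normal(
            spec.radius_mean_um, spec.radius_sd_um, int(bad.sum())
        )
    glom_radii = np.clip(glom_radii, lo_r, hi_r)
    for i in range(spec.n_glomeruli):
        border = i < spec.n_border_truncated
        r = float(glom_radii[i])
        c = place(r, border)
        lo, hi, grids = _ball_patch(shape, c, r / vs)
        if lo is None:
            raise PlacementError("planted glomerulus entirely outside grid")
        d = _sphere_distance_um(grids, c, vs)
        solid = d <= r
        shell = solid & (d >= r - spec.shell_thickness_um)
        patch = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        sub = image[patch]
        sub[shell] = spec.foreground_intensity
        interior = solid & ~shell
        sub[interior] = np.maximum(sub[interior], spec.interior_intensity)
        glom_labels[patch][solid] = i + 1
        count = int(solid.sum())
        rows.append(
            dict(
                object_id=i + 1,
                kind="glomerulus",
                center_z_um=c[0] * vs[0],
                center_y_um=c[1] * vs[1],
                center_x_um=c[2] * vs[2],
                radius_um=r,
                voxel_count=count,
                volume_um3=count * voxel_volume,
                border_truncated=border,
            )
        )

    bg_lo, bg_hi = spec.background_radius_um
    for j in range(spec.n_background_objects):
        r = float(rng.uniform(bg_lo, bg_hi))
        c = place(r, border=False)
        lo, hi, grids = _ball_patch(shape, c, r / vs)
        d = _sphere_distance_um(grids, c, vs)
        solid = d <= r
        patch = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        image[patch][solid] = spec.foreground_intensity
        count = int(solid.sum())
        rows.append(
            dict(
                object_id=spec.n_glomeruli + j + 1,
                kind="background",
                center_z_um=c[0] * vs[0],
                center_y_um=c[1] * vs[1],
                center_x_um=c[2] * vs[2],
                radius_um=r,
                voxel_count=count,
                volume_um3=count * voxel_volume,
                border_truncated=False,
            )
        )

    sigma_vox = np.array(spec.blur_sigma_um) / vs
    if np.any(sigma_vox > 0):
        image = ndi.gaussian_filter(image, sigma_vox, mode="nearest")
    if spec.poisson_gain > 0:
        image = rng.poisson(image * spec.poisson_gain) / spec.poisson_gain
    if spec.gaussian_sd > 0:
        image = image + rng.normal(0.0, spec.gaussian_sd, image.shape)
    image = np.clip(image, 0.0, None)

    stack = ImageStack3D(image, tuple(spec.voxel_size))
    truth = KidneyTruth(pd.DataFrame(rows), glom_labels, vessel_mask)
    return stack, truth


def generate_vessel_stack(
    spec: KidneySceneSpec | None = None, **overrides
) -> tuple[ImageStack3D, np.ndarray]:
    """Vessel-only scene (skin-like): tubes on dark background.

    Returns the stack and the planted tube mask. Any ``KidneySceneSpec``
    field may be overridden; glomeruli and background blobs default to zero
    and the tube count to six.
    """
    if spec is None:
        overrides.setdefault("n_glomeruli", 0)
        overrides.setdefault("n_border_truncated", 0)
        overrides.setdefault("n_background_objects", 0)
        overrides.setdefault("n_vessels", 6)
        spec = KidneySceneSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    stack, truth = generate_kidney_stack(spec)
    return stack, truth.vessel_mask


# ---------------------------------------------------------------------------
# 2D organ photographs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganPhotoSpec:
    """Parameters of a before/after organ photograph pair.

    The organ is a smooth irregular blob (low-order Fourier perturbation of
    a disk); the after-photo scales the contour radius by ``shrink_factor``
    about the same center. A bright ruler bar of ``ruler_length_px`` pixels
    stands for the 1-cm scale object; ``ruler_roi`` (derived) encloses it.
    """

    shape: tuple[int, int] = (512, 512)
    organ_center: tuple[float, float] = (320.0, 256.0)
    organ_radius_px: float = 90.0
    irregularity: float = 0.08
    shrink_factor: float = 0.85
    ruler_length_px: int = 100
    ruler_row: int = 20
    ruler_height_px: int = 16
    ruler_col: int = 50
    organ_intensity: float = 180.0
    background_intensity: float = 30.0
    ruler_intensity: float = 230.0
    illumination_amplitude: float = 0.10
    blur_sigma_px: float = 1.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.shrink_factor <= 2.0):
            raise InvalidParameterError("shrink_factor must lie in (0, 2]")
        if self.ruler_length_px < 2:
            raise InvalidParameterError("ruler_length_px must be >= 2")

    @property
    def ruler_roi(self) -> tuple[int, int, int, int]:
        """(row_start, row_stop, col_start, col_stop) around the ruler bar."""
        return (
            max(0, self.ruler_row - 10),
            self.ruler_row + self.ruler_height_px + 10,
            max(0, self.ruler_col - 12),
            self.ruler_col + self.ruler_length_px + 12,
        )


@dataclass(frozen=True)
class PhotoTruth:
    mask_before: np.ndarray
    mask_after: np.ndarray
    area_before_px: int
    area_after_px: int
    ruler_length_px: int

    @property
    def area_ratio(self) -> float:
        return self.area_after_px / self.area_before_px


def _blob_mask(spec: OrganPhotoSpec, harmonics, scale: float) -> np.ndarray:
    cy, cx = spec.organ_center
    yy, xx = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    boundary = np.full(theta.shape, spec.organ_radius_px)
    for k, (amp, phase) in harmonics.items():
        boundary = boundary + spec.organ_radius_px * amp * np.cos(k * theta + phase)
    return radius <= boundary * scale


def _render_photo(spec: OrganPhotoSpec, mask: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    img = np.full(spec.shape, float(spec.background_intensity))
    img[mask] = spec.organ_intensity
    r0, r1 = spec.ruler_row, spec.ruler_row + spec.ruler_height_px
    c0, c1 = spec.ruler_col, spec.ruler_col + spec.ruler_length_px
    img[r0:r1, c0:c1] = spec.ruler_intensity
    ramp = 1.0 + spec.illumination_amplitude * (
        np.linspace(0.0, 1.0, spec.shape[1]) - 0.5
    )
    img = img * ramp[None, :]
    if spec.blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma_px, mode="nearest")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 255.0)


def generate_organ_photo_pair(
    spec: OrganPhotoSpec,
) -> tuple[Image2D, Image2D, PhotoTruth]:
    """Render the before/after photographs and exact planted masks.

    The after-organ contour is the before-contour scaled by
    ``shrink_factor`` about the organ center, so the planted pixel-area
    ratio approaches ``shrink_factor²`` up to lattice digitization.
    """
    rng = np.random.default_rng(spec.seed)
    harmonics = {
        k: (spec.irregularity * rng.uniform(0.3, 1.0), rng.uniform(0, 2 * np.pi))
        for k in (2, 3, 4, 5)
    }
    mask_before = _blob_mask(spec, harmonics, 1.0)
    mask_after = _blob_mask(spec, harmonics, spec.shrink_factor)
    y0, y1, x0, x1 = spec.ruler_roi
    if mask_before[y0:y1, x0:x1].any():
        raise InvalidParameterError("organ blob overlaps the ruler ROI")
    before = Image2D(_render_photo(spec, mask_before, rng))
    after = Image2D(_render_photo(spec, mask_after, rng))
    truth = PhotoTruth(
        mask_before=mask_before,
        mask_after=mask_after,
        area_before_px=int(mask_before.sum()),
        area_after_px=int(mask_after.sum()),
        ruler_length_px=spec.ruler_length_px,
    )
    return before, after, truth
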