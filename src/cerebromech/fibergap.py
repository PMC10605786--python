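"""Empty-band quantification in elastic-fiber projection images.

A grayscale maximum-intensity projection of the elastin channel is
binarized, the arterial wall is aligned vertically (layers varying along
x), a rectangular region of interest is discretized into a 30 x 30 grid,
and the per-column mean area fraction of fiber-bearing pixels is computed.
Columns whose area fraction falls two standard deviations below the media
mean mark the fiber-depleted "empty band" at the media-adventitia
interface; its width is the run length times the column width times the
pixel size, averaged over several locations per sample.

Convention note: the source images show fibers as dark ("black") pixels
on a bright background after binarization in the original workflow; here
foreground always means *signal-bearing* (fiber) pixels, so the area
fraction counts fiber pixels regardless of display polarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import rotate as _sk_rotate

GRID = 30  # grid decomposition of the region of interest (rows x cols)


class FiberGapError(ValueError):
    pass


class ConstantImageError(FiberGapError):
    """No threshold can separate classes in a constant image."""


class AmbiguousBandError(FiberGapError):
    """More than one sub-threshold run spans the media-adventitia interface."""

    def __init__(self, runs: list[tuple[int, int]]):
        self.runs = runs
        super().__init__(
            f"multiple candidate bands at the media-adventitia interface: {runs}; "
            "tighten the annotation or inspect the profile"
        )


@dataclass(frozen=True)
class LayerAnnotation:
    """Pixel-column extents (start, stop) of each wall layer, wall aligned
    vertically so layers vary along x; half-open ranges, intima < media <
    adventitia."""

    intima: tuple[int, int]
    media: tuple[int, int]
    adventitia: tuple[int, int]

    def __post_init__(self) -> None:
        i, m, a = self.intima, self.media, self.adventitia
        if not (i[0] < i[1] <= m[0] < m[1] <= a[0] < a[1]):
            raise FiberGapError(
                f"layer ranges must be disjoint and ordered intima<media<adventitia: {i}, {m}, {a}"
            )


@dataclass(frozen=True)
class FiberImage:
    """Grayscale raster of an arterial cross-section with pixel size and
    layer annotation."""

    raster: np.ndarray
    pixel_size_um: float
    annotation: LayerAnnotation | None = None
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise FiberGapError("pixel size must be positive")
        if self.raster.ndim != 2:
            raise FiberGapError("raster must be 2-D grayscale")


@dataclass
class AreaFractionProfile:
    """Per-column mean fiber area fractions over a 30x30 ROI grid."""

    column_fractions: np.ndarray  # (GRID,)
    cell_fractions: np.ndarray  # (GRID, GRID)
    column_width_px: float
    pixel_size_um: float
    roi: tuple[int, int, int, int]  # (row0, row1, col0, col1)

    @property
    def column_width_um(self) -> float:
        return self.column_width_px * self.pixel_size_um


@dataclass
class GapMeasurement:
    band_columns: tuple[int, int] | None  # half-open grid-column run, None if no band
    width_um: float
    tau: float


def binarize(
    raster: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Threshold a grayscale image; foreground = fiber signal.

    Default is Otsu's between-class-variance-maximizing global threshold;
    pass ``threshold`` for a manual override.
    """
    raster = np.asarray(raster)
    if threshold is not None:
        return raster > threshold
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    if np.all(raster == raster.flat[0]):
        raise ConstantImageError("constant image: no threshold separates classes")
    return raster > threshold_otsu(raster)


def estimate_wall_angle(binary: np.ndarray) -> float:
    """Angle (degrees) of the foreground principal axis from vertical.

    Rotating the image by the returned angle aligns the wall vertically.
    """
    rows, cols = np.nonzero(binary)
    if rows.size < 2:
        return 0.0
    coords = np.stack([cols - cols.mean(), rows - rows.mean()])
    cov = coords @ coords.T / rows.size
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, -1]  # dominant axis (x, y components)
    return math.degrees(math.atan2(vx, vy))


def align_wall(image: FiberImage, angle_deg: float | None = None) -> FiberImage:
    """Rotate so the wall runs vertically; automatic principal-axis angle
    unless a manual angle is given."""
    if angle_deg is None:
        angle_deg = estimate_wall_angle(binarize(image.raster))
    rotated = _sk_rotate(image.raster.astype(float), -angle_deg, preserve_range=True)
    return FiberImage(
        raster=rotated,
        pixel_size_um=image.pixel_size_um,
        annotation=image.annotation,
        rotation_deg=image.rotation_deg + angle_deg,
    )


def area_fraction_profile(
    binary: np.ndarray,
    roi: tuple[int, int, int, int],
    pixel_size_um: float = 1.0,
) -> AreaFractionProfile:
    """Partition the ROI into a 30x30 grid and compute per-cell foreground
    fractions; each column value is the mean of its 30 cell fractions.

    Cell edges are placed by integer flooring of the ROI extent; remainder
    pixels are merged into the last row/column, so every ROI pixel counts
    exactly once.
    """
    row0, row1, col0, col1 = roi
    h, w = binary.shape
    if not (0 <= row0 < row1 <= h and 0 <= col0 < col1 <= w):
        raise FiberGapError(f"ROI {roi} outside image of shape {binary.shape}")
    if (row1 - row0) < GRID or (col1 - col0) < GRID:
        raise FiberGapError(f"ROI must be at least {GRID} px in each dimension")
    sub = np.asarray(binary[row0:row1, col0:col1], dtype=bool)
    ch = (row1 - row0) // GRID
    cw = (col1 - col0) // GRID
    cells = np.empty((GRID, GRID))
    for i in range(GRID):
        r_lo = i * ch
        r_hi = (i + 1) * ch if i < GRID - 1 else sub.shape[0]
        for j in range(GRID):
            c_lo = j * cw
            c_hi = (j + 1) * cw if j < GRID - 1 else sub.shape[1]
            cells[i, j] = sub[r_lo:r_hi, c_lo:c_hi].mean()
    return AreaFractionProfile(
        column_fractions=cells.mean(axis=0),
        cell_fractions=cells,
        column_width_px=cw,
        pixel_size_um=pixel_size_um,
        roi=roi,
    )


def _grid_columns(profile: AreaFractionProfile, pixel_range: tuple[int, int]) -> tuple[int, int]:
    """Map a pixel-column range to the half-open range of grid columns it
    overlaps (ROI-relative)."""
    _, _, col0, col1 = profile.roi
    cw = profile.column_width_px
    lo = max(int((pixel_range[0] - col0) // cw), 0)
    hi = min(int(math.ceil((pixel_range[1] - col0) / cw)), GRID)
    if hi <= lo:
        raise FiberGapError(f"pixel range {pixel_range} overlaps no grid column in ROI")
    return lo, hi


def media_threshold(
    profile: AreaFractionProfile,
    annotation: LayerAnnotation,
    mode: str = "per-image",
    pooled_mu: float | None = None,
    pooled_sd: float | None = None,
    include_adventitia: bool = False,
) -> float:
    """Empty-band threshold tau = mean - 2*SD of the media column fractions.

    SD uses the n-1 denominator.  ``mode="pooled"`` instead accepts
    externally supplied study-wide (mu, sigma) — e.g. pooled media
    statistics across all samples.  ``include_adventitia`` pools media and
    adventitia columns (sensitivity variant).
    """
    if mode == "pooled":
        if pooled_mu is None or pooled_sd is None:
            raise FiberGapError("pooled mode requires pooled_mu and pooled_sd")
        return pooled_mu - 2.0 * pooled_sd
    if mode != "per-image":
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = _grid_columns(profile, annotation.media)
    vals = list(profile.column_fractions[lo:hi])
    if include_adventitia:
        alo, ahi = _grid_columns(profile, annotation.adventitia)
        vals += list(profile.column_fractions[alo:ahi])
    vals = np.asarray(vals)
    if vals.size < 2:
        raise FiberGapError("need >=2 media columns to form a threshold")
    return float(vals.mean() - 2.0 * vals.std(ddof=1))


def detect_band(
    profile: AreaFractionProfile,
    tau: float,
    annotation: LayerAnnotation,
) -> GapMeasurement:
    """Find the sub-threshold column run at the media-adventitia interface.

    Among contiguous runs of columns with fraction < tau, the run
    intersecting the span between the annotated media and adventitia
    extents is the band; its width is run length x column width x pixel
    size.  No sub-threshold column there means the band is unnoticeable
    (width 0).  Several qualifying runs raise :class:`AmbiguousBandError`
    rather than picking one silently.
    """
    if not (0.0 < tau < 1.0):
        raise FiberGapError(f"threshold tau must lie in (0,1), got {tau}")
    below = profile.column_fractions < tau
    runs: list[tuple[int, int]] = []
    start = None
    for j, b in enumerate(below):
        if b and start is None:
            start = j
        elif not b and start is not None:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, GRID))

    _, m_hi = _grid_columns(profile, annotation.media)
    a_lo, _ = _grid_columns(profile, annotation.adventitia)
    # interface span: grid columns from the last media column to the first
    # adventitia column, inclusive of both edges so boundary bleed counts
    span_lo, span_hi = m_hi - 1, a_lo + 1
    candidates = [r for r in runs if r[0] < span_hi and r[1] > span_lo]
    if not candidates:
        return GapMeasurement(band_columns=None, width_um=0.0, tau=tau)
    if len(candidates) > 1:
        raise AmbiguousBandError(candidates)
    run = candidates[0]
    width = (run[1] - run[0]) * profile.column_width_um
    return GapMeasurement(band_columns=run, width_um=width, tau=tau)


def measure_sample(widths_um: Sequence[float]) -> tuple[float, float | None]:
    """Mean (and n-1 SD) of per-location band widths for one sample."""
    w = np.asarray(widths_um, dtype=float)
    if w.size == 0:
        raise FiberGapError("need at least one location")
    sd = float(w.std(ddof=1)) if w.size >= 2 else None
    return float(w.mean()), sd


def measure_gap(
    image: FiberImage,
    roi: tuple[int, int, int, int],
    threshold_mode: str = "per-image",
    pooled_mu: float | None = None,
    pooled_sd: float | None = None,
) -> tuple[GapMeasurement, AreaFractionProfile]:
    """Full single-image pipeline: binarize, profile, threshold, detect."""
    if image.annotation is None:
        raise FiberGapError("image needs a layer annotation to measure the gap")
    binary = binarize(image.raster)
    profile = area_fraction_profile(binary, roi, image.pixel_size_um)
    tau = media_threshold(
        profile, image.annotation, mode=threshold_mode, pooled_mu=pooled_mu, pooled_sd=pooled_sd
    )
    return detect_band(profile, tau, image.annotation), profile
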