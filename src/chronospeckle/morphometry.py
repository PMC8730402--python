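"""Nuclear speckle segmentation and sphericity morphometry.

Sphericity of a 2-D region is defined as

    sphericity = 2 * sqrt(pi * area) / perimeter

which is 1 for a perfect circle and tends to 0 for a line-like shape
(it is the square root of the isoperimetric quotient 4*pi*A/P**2).
Round "nucleation" droplets therefore score near 1 while connected
"spinodal" networks score low, making the area-weighted per-cell mean
a single morphology readout that can be followed over time.

Perimeters come from subpixel marching-squares contours, not from pixel
edge counting: edge counting overestimates the perimeter of a rasterized
disk by ~4/pi and would bias its sphericity to ~0.89 instead of the
anchor value 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure
from skimage.filters import threshold_otsu

from .timeseries import TimeSeries

__all__ = [
    "SpeckleRegion",
    "CellMorphometry",
    "sphericity",
    "contour_measure",
    "weighted_cell_sphericity",
    "segment_speckles",
    "temporal_sphericity",
]


@dataclass(frozen=True)
class SpeckleRegion:
    """One segmented speckle: subpixel contour area, perimeter, shape."""

    region_id: int
    area: float
    perimeter: float
    sphericity: float


@dataclass(frozen=True)
class CellMorphometry:
    """All speckles of one cell plus their area-weighted mean sphericity."""

    cell_id: int
    speckles: tuple[SpeckleRegion, ...]
    weighted_sphericity: float


def sphericity(area: float, perimeter: float) -> float:
    """``2*sqrt(pi*area)/perimeter``: 1 for a circle, -> 0 for a line."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 2.0 * math.sqrt(math.pi * area) / perimeter


def _polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed (row, col) contour."""
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_perimeter(contour: np.ndarray) -> float:
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


#: Gaussian pre-smoothing (px) applied to the mask before contouring.
#: The raw 0.5-level contour of a hard binary mask staircases along pixel
#: diagonals and overestimates a disk's perimeter by 7-14%, dragging its
#: sphericity to ~0.93; half-pixel-scale smoothing restores the circle
#: anchor to ~0.99 across radii while leaving elongated shapes unbiased.
_CONTOUR_SIGMA = 1.0


def contour_measure(mask: np.ndarray) -> tuple[float, float]:
    """(area, perimeter) of a binary region from its 0.5-level contour.

    The mask is padded so the contour closes even when the region
    touches the image border, lightly smoothed to suppress pixelation
    bias (see ``_CONTOUR_SIGMA``), and the largest-area contour (the
    outer boundary) is measured, so holes do not contribute.  Very thin
    regions that vanish under smoothing fall back to the raw contour.
    """
    padded = np.pad(mask.astype(float), 3)
    smoothed = gaussian_filter(padded, _CONTOUR_SIGMA)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask contains no region")
    outer = max(contours, key=_polygon_area)
    area = _polygon_area(outer)
    if area <= 0:
        raise ValueError("degenerate region contour")
    return area, _polygon_perimeter(outer)


def weighted_cell_sphericity(speckles: Sequence[SpeckleRegion]) -> float:
    """Area-weighted mean sphericity over a cell's speckles.

    Empty input reports missing (NaN) rather than 0: a cell without
    detected speckles has no shape, not a degenerate one.
    """
    if len(speckles) == 0:
        return math.nan
    areas = np.array([s.area for s in speckles])
    sph = np.array([s.sphericity for s in speckles])
    return float(np.sum(sph * areas) / np.sum(areas))


def segment_speckles(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    min_area: float = 4.0,
    threshold: str = "otsu",
    fixed_value: float | None = None,
) -> list[CellMorphometry]:
    """Segment speckles within each labeled nucleus and measure them.

    Each nucleus (positive label in ``nucleus_mask``) is thresholded
    independently (Otsu by default, or a fixed intensity), connected
    components are taken with 8-connectivity, components smaller than
    ``min_area`` pixels are dropped, and area/perimeter are measured on
    the subpixel 0.5-level contour of each component.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if nucleus_mask.shape != image.shape:
        raise ValueError("nucleus_mask shape must match image")
    cells: list[CellMorphometry] = []
    for cell_id in np.unique(nucleus_mask):
        if cell_id <= 0:
            continue
        inside = nucleus_mask == cell_id
        pix = image[inside]
        if threshold == "otsu":
            if np.ptp(pix) == 0:
                cells.append(CellMorphometry(int(cell_id), (), math.nan))
                continue
            thr = threshold_otsu(pix)
        elif threshold == "fixed":
            if fixed_value is None:
                raise ValueError("fixed threshold requires fixed_value")
            thr = fixed_value
        else:
            raise ValueError(f"unknown threshold method {threshold!r}")
        binary = (image > thr) & inside
        labels = measure.label(binary, connectivity=2)
        regions = []
        rid = 0
        for props in measure.regionprops(labels):
            if props.area < min_area:
                continue
            rid += 1
            comp = labels == props.label
            area, perim = contour_measure(comp)
            if area <= 0 or perim <= 0:
                continue
            regions.append(SpeckleRegion(rid, area, perim, sphericity(area, perim)))
        cells.append(
            CellMorphometry(int(cell_id), tuple(regions), weighted_cell_sphericity(regions))
        )
    return cells


def temporal_sphericity(
    images: Sequence[np.ndarray] | np.ndarray,
    nucleus_masks: Sequence[np.ndarray] | np.ndarray,
    times: np.ndarray | None = None,
    min_area: float = 4.0,
    threshold: str = "otsu",
    fixed_value: float | None = None,
) -> tuple[dict[int, TimeSeries], TimeSeries]:
    """Per-cell and population-mean sphericity series over a movie.

    Frames are segmented independently (no cross-frame tracking); the
    population series averages the cells present in each frame.  Cells
    with no speckles in a frame hold NaN in their own series and are
    excluded from that frame's population mean.
    """
    n_frames = len(images)
    if len(nucleus_masks) == 1 and n_frames > 1:
        nucleus_masks = [nucleus_masks[0]] * n_frames
    if len(nucleus_masks) != n_frames:
        raise ValueError("need one nucleus mask per frame (or a single static mask)")
    if times is None:
        times = np.arange(n_frames, dtype=float)
    times = np.asarray(times, dtype=float)

    per_cell: dict[int, list[float]] = {}
    pop = np.full(n_frames, np.nan)
    for f in range(n_frames):
        cells = segment_speckles(
            images[f], nucleus_masks[f], min_area=min_area,
            threshold=threshold, fixed_value=fixed_value,
        )
        vals = []
        for cell in cells:
            per_cell.setdefault(cell.cell_id, [math.nan] * n_frames)
        for cell in cells:
            per_cell[cell.cell_id][f] = cell.weighted_sphericity
            if not math.isnan(cell.weighted_sphericity):
                vals.append(cell.weighted_sphericity)
        if vals:
            pop[f] = float(np.mean(vals))
    cell_series = {cid: TimeSeries(times, np.array(v)) for cid, v in sorted(per_cell.items())}
    return cell_series, TimeSeries(times, pop)
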