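"""Calibrated B-mode images, tendon ROIs and lateral-margin trimming.

The measurement protocol outlines the tendon within its hyperechoic
epitenon and then restricts the region of interest (ROI) to a fixed
physical width centred on the imaged (most painful) site: 10 mm in the
longitudinal plane and 5 mm in the transverse plane.  This module holds
the two carrier types (:class:`CalibratedImage`, :class:`RegionOfInterest`)
and the geometric operations: polygon rasterisation, lateral trimming and
construction of ROI polygons from simulator ground truth.

Coordinate convention: row-major pixel grid, 0-based indices, pixel
centres at integer coordinates, row 0 on the superficial (skin) side.
Polygon vertices are ``(row, col)`` pairs in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .errors import InsufficientWidthError, InvalidParameterError, InvalidROIError

LONGITUDINAL = "longitudinal"
TRANSVERSE = "transverse"
PLANES = (LONGITUDINAL, TRANSVERSE)

#: Physical ROI width after lateral trimming, by imaging plane (mm).
TRIM_WIDTH_MM = {LONGITUDINAL: 10.0, TRANSVERSE: 5.0}


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit grayscale B-mode frame with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Gray levels, row 0 = superficial side.
    row_spacing_mm, col_spacing_mm : float
        Physical size of one pixel along depth and width.
    plane : {"longitudinal", "transverse"}
    side : {"symptomatic", "asymptomatic"}, optional
    image_index : int, optional
        1..3 within a triplicate.
    """

    pixels: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    plane: str
    side: str | None = None
    image_index: int | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidParameterError("pixels must be a 2-D raster")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidParameterError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise InvalidParameterError("pixel spacings must be positive")
        if self.plane not in PLANES:
            raise InvalidParameterError(f"unknown plane {self.plane!r}")
        if self.image_index is not None and not 1 <= self.image_index <= 3:
            raise InvalidParameterError("image_index must be 1..3")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Polygon plus congruent boolean mask delimiting the tendon."""

    polygon: np.ndarray  # (n, 2) float array of (row, col) vertices
    mask: np.ndarray     # boolean raster, same shape as the image

    def __post_init__(self):
        object.__setattr__(self, "polygon", np.asarray(self.polygon, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise InvalidROIError("polygon must be an (n, 2) vertex array")
        if not self.mask.any():
            raise InvalidROIError("ROI mask is empty")

    @property
    def column_extent(self) -> tuple[int, int]:
        """(first, last) column index holding at least one true pixel."""
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(cols[0]), int(cols[-1])

    def width_columns(self) -> int:
        lo, hi = self.column_extent
        return hi - lo + 1


def _shapely_polygon(polygon: np.ndarray) -> shapely.Polygon:
    # shapely works in (x, y) = (col, row)
    poly = shapely.Polygon([(c, r) for r, c in polygon])
    if not poly.is_valid:
        raise InvalidROIError("polygon is self-intersecting or otherwise invalid")
    if poly.area == 0:
        raise InvalidROIError("polygon has zero area")
    return poly


def rasterize_roi(polygon: Sequence[Sequence[float]], image: CalibratedImage) -> RegionOfInterest:
    """Rasterise a simple polygon onto the image grid.

    The mask is true exactly for pixel centres covered by the polygon,
    boundary points included.

    Raises
    ------
    InvalidROIError
        For polygons with fewer than three vertices, zero area,
        self-intersections, or vertices outside the image bounds.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[1] != 2 or len(polygon) < 3:
        raise InvalidROIError("polygon needs at least three (row, col) vertices")
    rows, cols = image.shape
    if (polygon[:, 0].min() < 0 or polygon[:, 0].max() > rows - 1
            or polygon[:, 1].min() < 0 or polygon[:, 1].max() > cols - 1):
        raise InvalidROIError("polygon vertices fall outside the image bounds")
    poly = _shapely_polygon(polygon)

    # test only pixel centres inside the polygon's bounding box
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = int(np.floor(minx)), int(np.ceil(maxx))
    r0, r1 = int(np.floor(miny)), int(np.ceil(maxy))
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(cc.ravel(), rr.ravel())
    inside = shapely.covers(poly, pts).reshape(rr.shape)

    mask = np.zeros(image.shape, dtype=bool)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    if not mask.any():
        raise InvalidROIError("polygon covers no pixel centre")
    return RegionOfInterest(polygon=polygon, mask=mask)


def width_in_columns(target_mm: float, col_spacing_mm: float) -> int:
    """Nearest-integer column count for a physical width."""
    return int(round(target_mm / col_spacing_mm))


def trim_lateral_margins(
    roi: RegionOfInterest,
    image: CalibratedImage,
    target_width_mm: float | None = None,
) -> RegionOfInterest:
    """Restrict an ROI to a contiguous column band of fixed physical width.

    The band is ``round(target / col_spacing)`` columns wide, centred on
    the column centroid of the mask (ties broken toward the lower column
    index) and shifted, if necessary, to stay inside the ROI's own column
    extent.  Vertical extents within the band are untouched, so trimming
    an already-trimmed ROI is the identity.

    Raises
    ------
    InsufficientWidthError
        If the ROI's horizontal extent is narrower than the target width;
        the error names the shortfall in millimetres.
    """
    if target_width_mm is None:
        target_width_mm = TRIM_WIDTH_MM[image.plane]
    width_cols = width_in_columns(target_width_mm, image.col_spacing_mm)
    col_any = roi.mask.any(axis=0)
    occupied = np.flatnonzero(col_any)
    lo, hi = int(occupied[0]), int(occupied[-1])
    extent_cols = hi - lo + 1
    if extent_cols < width_cols:
        shortfall = (width_cols - extent_cols) * image.col_spacing_mm
        raise InsufficientWidthError(
            f"ROI spans {extent_cols * image.col_spacing_mm:.2f} mm, "
            f"{shortfall:.2f} mm short of the {target_width_mm:g} mm target",
            shortfall_mm=shortfall,
        )
    counts = roi.mask.sum(axis=0)
    centroid = float(np.average(np.arange(roi.mask.shape[1]), weights=counts))
    # ideal left edge; round half toward the lower column index
    start = int(np.ceil(centroid - (width_cols - 1) / 2.0 - 0.5))
    start = min(max(start, lo), hi - width_cols + 1)

    band = np.zeros_like(col_any)
    band[start:start + width_cols] = True
    mask = roi.mask & band[np.newaxis, :]
    kept = np.flatnonzero(mask.any(axis=0))
    if kept.size < width_cols:
        empty = sorted(set(range(start, start + width_cols)) - set(kept.tolist()))
        raise InvalidROIError(f"columns {empty} inside the trim band hold no ROI pixel")
    return RegionOfInterest(polygon=roi.polygon, mask=mask)


@dataclass(frozen=True)
class BoundaryCurves:
    """Per-column superior/inferior tendon boundary rows (ground truth)."""

    cols: np.ndarray      # int columns where the tendon band is present
    superior: np.ndarray  # first (shallowest) row of the band, per column
    inferior: np.ndarray  # last (deepest) row of the band, per column

    def __post_init__(self):
        for name in ("cols", "superior", "inferior"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        if not (self.cols.shape == self.superior.shape == self.inferior.shape):
            raise InvalidParameterError("boundary arrays must share a shape")
        if np.any(self.inferior < self.superior):
            raise InvalidParameterError("inferior boundary above superior boundary")

    thickness_rows = property(lambda self: self.inferior - self.superior + 1)


def roi_from_ground_truth(
    boundaries: BoundaryCurves,
    lateral_extent: tuple[int, int] | None = None,
) -> np.ndarray:
    """Build an ROI polygon tracing ground-truth boundary curves.

    Stands in for the manual outlining step: the polygon follows the
    superior curve left to right over ``lateral_extent = (first_col,
    last_col)`` (inclusive; default the full rendered extent), then the
    inferior curve right to left, closed implicitly.
    """
    cols = boundaries.cols
    if lateral_extent is None:
        lateral_extent = (int(cols[0]), int(cols[-1]))
    c0, c1 = lateral_extent
    if c0 > c1:
        raise InvalidParameterError("lateral_extent must satisfy first <= last")
    if c0 < cols[0] or c1 > cols[-1]:
        raise InvalidParameterError(
            f"lateral extent [{c0}, {c1}] outside rendered band columns "
            f"[{cols[0]}, {cols[-1]}]")
    sel = (cols >= c0) & (cols <= c1)
    cs = cols[sel]
    top = boundaries.superior[sel]
    bot = boundaries.inferior[sel]
    upper = np.column_stack([top, cs])
    lower = np.column_stack([bot[::-1], cs[::-1]])
    return np.vstack([upper, lower]).astype(float)
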