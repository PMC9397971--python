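"""Minimal musculoskeletal-ultrasound-biomarker (MUB) dataset per image.

Three biomarkers summarise one trimmed tendon ROI:

* **mean thickness** (geometric, mm) — mean over retained columns of the
  superior-to-inferior pixel extent, scaled by the depth calibration;
* **echogenicity** (composition, 0–255) — mean raw gray level over the mask;
* **homogeneity** (texture, 0–1) — the gray-level co-occurrence matrix
  (GLCM) statistic Σ P(i,j)/(1+(i−j)²), evaluated at 90° (the depth axis,
  perpendicular to the fibre direction) in the longitudinal plane and as
  the multidirectional mean over {0°, 45°, 90°, 135°} in the transverse
  plane.

The GLCM here respects the ROI mask — a pair contributes only when both
pixels lie inside the mask — which is why it is implemented locally
rather than delegated to :func:`skimage.feature.graycomatrix` (used in the
test suite as an independent cross-check on rectangular masks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, InvalidROIError
from .geometry import (
    LONGITUDINAL,
    PLANES,
    TRANSVERSE,
    TRIM_WIDTH_MM,
    CalibratedImage,
    RegionOfInterest,
    width_in_columns,
)

#: pixel offset (drow, dcol) per co-occurrence angle, for distance d=1
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

KERNEL_INVERSE_SQUARE = "inverse_square"  # 1 / (1 + (i-j)^2)
KERNEL_INVERSE_ABS = "inverse_abs"        # 1 / (1 + |i-j|)


@dataclass(frozen=True)
class GLCMSpec:
    """Configuration of the co-occurrence computation.

    The source acquisition program fixes only the 90°/multidirectional
    angle convention; distance, level count, symmetry and the exact
    homogeneity kernel are conventional defaults, deliberately exposed.
    """

    distance_px: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 64
    symmetric: bool = True
    kernel: str = KERNEL_INVERSE_SQUARE

    def __post_init__(self):
        if self.distance_px < 1:
            raise InvalidParameterError("distance_px must be a positive integer")
        if not self.angles:
            raise InvalidParameterError("angle set must be non-empty")
        if any(a not in _ANGLE_OFFSETS for a in self.angles):
            raise InvalidParameterError(f"angles must be a subset of {sorted(_ANGLE_OFFSETS)}")
        if self.levels < 2:
            raise InvalidParameterError("levels must be >= 2")
        if self.kernel not in (KERNEL_INVERSE_SQUARE, KERNEL_INVERSE_ABS):
            raise InvalidParameterError(f"unknown homogeneity kernel {self.kernel!r}")


@dataclass(frozen=True)
class BiomarkerSet:
    """Thickness, echogenicity and homogeneity for one plane (one image
    or a triplicate average)."""

    mean_thickness_mm: float
    echogenicity: float
    homogeneity: float
    plane: str
    side: str | None = None
    n_images_averaged: int = 1

    def __post_init__(self):
        if self.mean_thickness_mm <= 0:
            raise InvalidParameterError("mean thickness must be positive")
        if not 0 <= self.echogenicity <= 255:
            raise InvalidParameterError("echogenicity must lie in [0, 255]")
        if not 0 <= self.homogeneity <= 1:
            raise InvalidParameterError("homogeneity must lie in [0, 1]")
        if self.plane not in PLANES:
            raise InvalidParameterError(f"unknown plane {self.plane!r}")
        if not 1 <= self.n_images_averaged <= 3:
            raise InvalidParameterError("n_images_averaged must be 1..3")


def _column_extents(roi: RegionOfInterest) -> np.ndarray:
    """Superior-to-inferior extent (rows, inclusive) per occupied column."""
    mask = roi.mask
    lo, hi = roi.column_extent
    extents = np.empty(hi - lo + 1, dtype=float)
    for k, c in enumerate(range(lo, hi + 1)):
        rows = np.flatnonzero(mask[:, c])
        if rows.size == 0:
            raise InvalidROIError(f"column {c} inside the ROI band holds no pixel")
        extents[k] = rows[-1] - rows[0] + 1
    return extents


def mean_thickness(roi: RegionOfInterest, image: CalibratedImage,
                   method: str = "extent") -> float:
    """Mean tendon thickness over the retained columns, in millimetres.

    ``method="extent"`` (default) averages the per-column
    superior-to-inferior pixel extent, so interior mask holes do not
    shrink the estimate — thickness is an envelope measure of the
    epitenon-bounded ROI.  ``method="area"`` divides the mask area by the
    band width instead.
    """
    if method == "extent":
        return float(image.row_spacing_mm * _column_extents(roi).mean())
    if method == "area":
        lo, hi = roi.column_extent
        return float(image.row_spacing_mm * roi.mask.sum() / (hi - lo + 1))
    raise InvalidParameterError(f"unknown thickness method {method!r}")


def echogenicity(roi: RegionOfInterest, image: CalibratedImage) -> float:
    """Arithmetic mean of the raw 8-bit gray levels over the mask."""
    if not roi.mask.any():
        raise InvalidROIError("empty mask")
    return float(image.pixels[roi.mask].mean())


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of 8-bit intensities into ``levels`` gray levels."""
    return (pixels.astype(np.int64) * levels) // 256


def glcm(roi: RegionOfInterest, image: CalibratedImage, spec: GLCMSpec,
         angle: int) -> np.ndarray:
    """Normalised gray-level co-occurrence matrix at one angle.

    Counts ordered pixel pairs ``(p, p + offset)`` with *both* pixels
    inside the ROI mask; the offset per angle (distance ``d``) is
    0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0), 135° → (−d, −d).
    If ``spec.symmetric``, each pair is also counted in the reverse
    direction.  The matrix is normalised to sum 1.
    """
    if angle not in _ANGLE_OFFSETS:
        raise InvalidParameterError(f"unsupported angle {angle}")
    d = spec.distance_px
    dr, dc = (o * d for o in _ANGLE_OFFSETS[angle])
    q = quantize(image.pixels, spec.levels)
    mask = roi.mask

    rows, cols = mask.shape
    # source window such that both p and p+offset are in bounds
    src = np.zeros_like(mask)
    rs = slice(max(0, -dr), rows - max(0, dr))
    cs = slice(max(0, -dc), cols - max(0, dc))
    src[rs, cs] = True
    valid = src & mask & np.roll(np.roll(mask, -dr, axis=0), -dc, axis=1)
    if not valid.any():
        raise InvalidROIError("no co-occurring pixel pair admits this offset")

    i = q[valid]
    j = np.roll(np.roll(q, -dr, axis=0), -dc, axis=1)[valid]
    counts = np.zeros((spec.levels, spec.levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def homogeneity(glcm_matrix: np.ndarray, kernel: str = KERNEL_INVERSE_SQUARE) -> float:
    """Homogeneity statistic of a normalised GLCM.

    Default kernel Σ P(i,j) / (1 + (i−j)²); equals 1 iff all
    co-occurrence mass lies on the diagonal.
    """
    P = np.asarray(glcm_matrix, dtype=float)
    if abs(P.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("GLCM must be normalised to sum 1")
    i, j = np.indices(P.shape)
    if kernel == KERNEL_INVERSE_SQUARE:
        w = 1.0 / (1.0 + (i - j) ** 2)
    elif kernel == KERNEL_INVERSE_ABS:
        w = 1.0 / (1.0 + np.abs(i - j))
    else:
        raise InvalidParameterError(f"unknown homogeneity kernel {kernel!r}")
    return float((P * w).sum())


def _check_trimmed(roi: RegionOfInterest, image: CalibratedImage) -> None:
    expected = width_in_columns(TRIM_WIDTH_MM[image.plane], image.col_spacing_mm)
    if roi.width_columns() != expected:
        raise InvalidROIError(
            f"ROI spans {roi.width_columns()} columns but the {image.plane} "
            f"plane requires a trimmed band of {expected} columns "
            f"({TRIM_WIDTH_MM[image.plane]:g} mm)")


def extract_biomarkers(image: CalibratedImage, roi: RegionOfInterest,
                       spec: GLCMSpec | None = None) -> BiomarkerSet:
    """Compute the minimal MUB set for one trimmed ROI.

    Homogeneity is evaluated at 90° for longitudinal images and as the
    mean over the spec's angle set for transverse images.
    """
    spec = spec or GLCMSpec()
    _check_trimmed(roi, image)
    if image.plane == LONGITUDINAL:
        h = homogeneity(glcm(roi, image, spec, 90), spec.kernel)
    else:
        h = float(np.mean([homogeneity(glcm(roi, image, spec, a), spec.kernel)
                           for a in spec.angles]))
    return BiomarkerSet(
        mean_thickness_mm=mean_thickness(roi, image),
        echogenicity=echogenicity(roi, image),
        homogeneity=h,
        plane=image.plane,
        side=image.side,
        n_images_averaged=1,
    )


def average_triplicate(sets: list[BiomarkerSet]) -> BiomarkerSet:
    """Field-wise mean of the (nominally three) per-image biomarker sets."""
    if not 2 <= len(sets) <= 3:
        raise InvalidParameterError("triplicate averaging expects 2 or 3 sets")
    planes = {s.plane for s in sets}
    if len(planes) != 1:
        raise InvalidParameterError(f"mixed planes {sorted(planes)} cannot be averaged")
    sides = {s.side for s in sets}
    if len(sides) != 1:
        raise InvalidParameterError(f"mixed sides {sorted(map(str, sides))} cannot be averaged")
    if len(sets) == 2:
        warnings.warn("averaging only 2 images instead of the nominal 3", stacklevel=2)
    return BiomarkerSet(
        mean_thickness_mm=float(np.mean([s.mean_thickness_mm for s in sets])),
        echogenicity=float(np.mean([s.echogenicity for s in sets])),
        homogeneity=float(np.mean([s.homogeneity for s in sets])),
        plane=sets[0].plane,
        side=sets[0].side,
        n_images_averaged=len(sets),
    )
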