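"""Detection and cropping of elliptical microwells.

Wells are dark elliptical rims (nominal 250 x 150 um footprint) on a bright
background.  Because the geometry is known a priori, detection is
model-based: dark regions are thresholded (Otsu), rims are filled into
solid elliptical blobs, a moment-based ellipse is fitted to each blob
(``skimage.measure.regionprops``), and candidates are gated by the expected
axis lengths and aspect ratio.  The fitted outer ellipse is shrunk by the
rim width to recover the well *interior*, which defines both the crop
rectangle and the well mask used for pixel counting.

Coordinate conventions: row-major, 0-based; bounding boxes are half-open
``(row0, col0, row1, col1)``; ``center_xy_px`` is ``(x, y) == (col, row)``;
``angle_deg`` is the major axis angle versus the image x-axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .image_correction import CorrectedImage

ASPECT_RANGE = (1.2, 2.3)

#: Pixels darker than this fraction of the robust background level (99th
#: percentile) are rim/cluster candidates during well detection.
DARK_FRACTION = 0.6


@dataclass(frozen=True)
class WellROI:
    center_xy_px: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    angle_deg: float
    bbox: tuple[int, int, int, int]

    def __post_init__(self):
        if not (self.semi_major_px >= self.semi_minor_px > 0):
            raise ValueError("need semi_major_px >= semi_minor_px > 0")


@dataclass(frozen=True)
class WellImage:
    """A crop of the corrected frame at one well's tangent rectangle."""

    pixels: np.ndarray
    roi: WellROI
    well_mask: np.ndarray
    sample_id: str = ""
    well_id: str = ""

    def __post_init__(self):
        if self.pixels.shape != self.well_mask.shape:
            raise ValueError("well_mask must match crop shape")
        if int(self.well_mask.sum()) < 1:
            raise ValueError("well_mask has no interior pixels")


def _tangent_bbox(cx, cy, a, b, angle_deg, shape):
    """Axis-aligned tangent rectangle of a rotated ellipse, clipped to frame."""
    phi = math.radians(angle_deg)
    ex = math.sqrt((a * math.cos(phi)) ** 2 + (b * math.sin(phi)) ** 2)
    ey = math.sqrt((a * math.sin(phi)) ** 2 + (b * math.cos(phi)) ** 2)
    r0 = int(math.floor(cy - ey))
    c0 = int(math.floor(cx - ex))
    r1 = int(math.ceil(cy + ey)) + 1
    c1 = int(math.ceil(cx + ex)) + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, shape[0]), min(c1, shape[1])
    return (r0c, c0c, r1c, c1c)


def make_roi(cx, cy, a, b, angle_deg, image_shape) -> WellROI:
    """Build a :class:`WellROI` with its tangent bbox clipped to the frame."""
    return WellROI(
        center_xy_px=(float(cx), float(cy)),
        semi_major_px=float(a),
        semi_minor_px=float(b),
        angle_deg=float(angle_deg),
        bbox=_tangent_bbox(cx, cy, a, b, angle_deg, image_shape),
    )


def _ellipse_mask(shape, origin_rc, cx, cy, a, b, angle_deg):
    rows = np.arange(origin_rc[0], origin_rc[0] + shape[0])
    cols = np.arange(origin_rc[1], origin_rc[1] + shape[1])
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    phi = math.radians(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _clip_fraction(cx, cy, a, b, angle_deg, shape):
    """Fraction of the (unclipped) ellipse interior falling outside the frame."""
    phi = math.radians(angle_deg)
    ex = math.sqrt((a * math.cos(phi)) ** 2 + (b * math.sin(phi)) ** 2)
    ey = math.sqrt((a * math.sin(phi)) ** 2 + (b * math.cos(phi)) ** 2)
    r0, c0 = int(math.floor(cy - ey)), int(math.floor(cx - ex))
    r1, c1 = int(math.ceil(cy + ey)) + 1, int(math.ceil(cx + ex)) + 1
    mask = _ellipse_mask((r1 - r0, c1 - c0), (r0, c0), cx, cy, a, b, angle_deg)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    inside_frame = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    total = int(mask.sum())
    if total == 0:
        return 1.0
    return 1.0 - int((mask & inside_frame).sum()) / total


def detect_wells(
    img: CorrectedImage,
    expected_major_um: float = 250.0,
    expected_minor_um: float = 150.0,
    pixel_size_um: float | None = None,
    tolerance_frac: float = 0.3,
    rim_px: float = 3.0,
    max_clip_frac: float = 0.4,
) -> list[WellROI]:
    """Find microwells whose fitted geometry matches the expected one.

    Returns ROIs describing each well *interior* (fitted rim ellipse shrunk
    by ``rim_px``), sorted in raster order (row bands, then column).  An
    empty list is a valid result.
    """
    if expected_major_um <= 0 or expected_minor_um <= 0:
        raise ValueError("expected axes must be positive")
    if not (0 < tolerance_frac <= 0.5):
        raise ValueError("tolerance_frac must be in (0, 0.5]")
    if pixel_size_um is None:
        pixel_size_um = img.pixel_size_um
    px = img.pixels
    if px.max() - px.min() < 1e-6:
        return []

    exp_a = expected_major_um / 2.0 / pixel_size_um
    exp_b = expected_minor_um / 2.0 / pixel_size_um

    # Rims are far darker than the (corrected, hence flat) background; a
    # fixed fraction of the robust background level separates them reliably
    # even when the histogram is degenerate (noise-free synthetic frames
    # defeat Otsu because the dark class is tiny).
    dark = px < DARK_FRACTION * np.percentile(px, 99.0)
    filled = ndi.binary_fill_holes(dark)
    labels = measure.label(filled)

    candidates = []
    for prop in measure.regionprops(labels):
        a_out = prop.axis_major_length / 2.0
        b_out = prop.axis_minor_length / 2.0
        a, b = a_out - rim_px, b_out - rim_px
        if a <= 0 or b <= 0:
            continue
        if abs(a - exp_a) > tolerance_frac * exp_a:
            continue
        if abs(b - exp_b) > tolerance_frac * exp_b:
            continue
        aspect = a / b
        if not (ASPECT_RANGE[0] <= aspect <= ASPECT_RANGE[1]):
            continue
        cy, cx = prop.centroid
        # regionprops orientation: angle of major axis vs row axis, ccw.
        angle_deg = (90.0 - math.degrees(prop.orientation)) % 180.0
        if angle_deg >= 90.0:
            angle_deg -= 180.0
        if _clip_fraction(cx, cy, a, b, angle_deg, px.shape) > max_clip_frac:
            continue
        fit_err = abs(a - exp_a) / exp_a + abs(b - exp_b) / exp_b
        candidates.append((fit_err, cx, cy, a, b, angle_deg))

    # merge overlapping detections, keeping the better-fitting one
    candidates.sort(key=lambda t: t[0])
    kept = []
    for cand in candidates:
        _, cx, cy, a, b, _ = cand
        if any(math.hypot(cx - k[1], cy - k[2]) < 2.0 * min(b, k[4]) for k in kept):
            continue
        kept.append(cand)

    rois = [make_roi(cx, cy, a, b, ang, px.shape) for _, cx, cy, a, b, ang in kept]
    # raster order: group into row bands (within one semi-minor axis), then by x
    rois.sort(key=lambda r: r.center_xy_px[1])
    bands: list[list[WellROI]] = []
    for roi in rois:
        if bands and abs(roi.center_xy_px[1] - bands[-1][0].center_xy_px[1]) < roi.semi_minor_px:
            bands[-1].append(roi)
        else:
            bands.append([roi])
    out = []
    for band in bands:
        out.extend(sorted(band, key=lambda r: r.center_xy_px[0]))
    return out


def crop_well(
    img: CorrectedImage,
    roi: WellROI,
    sample_id: str = "",
    well_id: str = "",
) -> WellImage:
    """Crop the tangent rectangle of a well and rasterize its interior mask."""
    r0, c0, r1, c1 = roi.bbox
    if r1 <= r0 or c1 <= c0 or r0 >= img.pixels.shape[0] or c0 >= img.pixels.shape[1]:
        raise ValueError(f"ROI bbox {roi.bbox} lies outside the image")
    crop = img.pixels[r0:r1, c0:c1]
    cx, cy = roi.center_xy_px
    mask = _ellipse_mask(
        crop.shape, (r0, c0), cx, cy, roi.semi_major_px, roi.semi_minor_px, roi.angle_deg
    )
    return WellImage(pixels=crop, roi=roi, well_mask=mask, sample_id=sample_id, well_id=well_id)
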