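"""Image loading and flat-field illumination correction.

Microwell-array micrographs show a smooth, vignetted illumination field on
top of which the (much smaller) wells and clusters sit.  Gray-value
phenotypes are only comparable across a frame once that field is removed.
The background is estimated with a wide Gaussian blur (sigma defaulting to
width/8, large relative to a well so well-scale objects barely contaminate
the estimate), subtracted, and the mean background level added back so that
absolute gray levels stay meaningful for downstream normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

# ITU-R BT.601 luminance weights for RGB -> gray
_LUMA = np.array([0.2989, 0.5870, 0.1140])

_MIN_SIDE = 64


@dataclass(frozen=True)
class RawImage:
    """A loaded micrograph, intensities scaled to [0, 1].

    Parameters
    ----------
    pixels : 2-D float array in [0, 1]
    pixel_size_um : physical side of one pixel in micrometres
    source_path : where the image came from ("" for synthetic frames)
    """

    pixels: np.ndarray
    pixel_size_um: float
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D gray image, got shape {px.shape}")
        if min(px.shape) < _MIN_SIDE:
            raise ValueError(
                f"image too small ({px.shape}); need at least {_MIN_SIDE} px per side"
            )
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CorrectedImage:
    """A flat-field corrected frame plus the estimated illumination field."""

    pixels: np.ndarray
    background: np.ndarray
    correction_sigma_px: float
    pixel_size_um: float
    source_path: str = ""

    def __post_init__(self):
        if self.pixels.shape != self.background.shape:
            raise ValueError("background must match image shape")
        if not np.all(self.background > 0):
            raise ValueError("estimated background must be strictly positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ValueError(f"cannot interpret channel axis of shape {arr.shape}")
        return arr @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {arr.shape}")
    return arr


def load_image(path: str | Path, pixel_size_um: float) -> RawImage:
    """Read a TIFF or PNG micrograph and rescale intensities to [0, 1].

    Integer containers are divided by their full-scale value (255 for 8-bit,
    65535 for 16-bit); float containers are assumed to already be in [0, 1]
    and are clipped.  RGB frames are converted to gray with the standard
    luminance weights 0.2989/0.5870/0.1140.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            arr = iio.imread(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if np.issubdtype(arr.dtype, np.integer):
        full_scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float) / full_scale
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    gray = np.clip(_to_gray(arr), 0.0, 1.0)
    return RawImage(pixels=gray, pixel_size_um=pixel_size_um, source_path=str(path))


def flatfield_correct(
    img: RawImage | CorrectedImage,
    sigma_px: float | None = None,
    mode: str = "subtract",
) -> CorrectedImage:
    """Remove the smooth illumination field from a frame.

    ``mode="subtract"`` (default): ``corrected = img - blur + mean(blur)``,
    which keeps mean brightness and leaves absolute gray levels meaningful.
    ``mode="divide"``: ``corrected = img / blur * mean(blur)``, the classical
    multiplicative shading model.  Both results are clipped to [0, 1].
    """
    px = img.pixels
    if sigma_px is None:
        sigma_px = px.shape[1] / 8.0
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    if mode not in ("subtract", "divide"):
        raise ValueError(f"unknown correction mode {mode!r}")

    # Odd-reflection padding continues the illumination gradient across the
    # frame edge; plain nearest/reflect padding flattens it and leaves a
    # border band in the corrected image.
    pad = max(int(math.ceil(3 * sigma_px)), 1)
    pad = min(pad, min(px.shape) - 1)
    padded = np.pad(px, pad, mode="reflect", reflect_type="odd")
    background = ndi.gaussian_filter(padded, sigma=sigma_px, mode="nearest")
    background = background[pad:-pad, pad:-pad]
    background = np.maximum(background, 1e-6)
    level = float(background.mean())
    if mode == "subtract":
        corrected = px - background + level
    else:
        corrected = px / background * level
    corrected = np.clip(corrected, 0.0, 1.0)
    return CorrectedImage(
        pixels=corrected,
        background=background,
        correction_sigma_px=float(sigma_px),
        pixel_size_um=img.pixel_size_um,
        source_path=getattr(img, "source_path", ""),
    )


def write_corrected(img: CorrectedImage, path: str | Path) -> None:
    """Persist a corrected frame as 16-bit TIFF."""
    import tifffile

    arr = np.clip(img.pixels, 0.0, 1.0)
    tifffile.imwrite(str(path), (arr * 65535.0 + 0.5).astype(np.uint16))
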