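"""Image preprocessing: the three variants fed independently to OCR.

A label photograph is decoded into three single-channel variants before
recognition: plain greyscale, a 3×3 sharpened version (helps poorly focussed
photos) and a 3×3 box-blurred version followed by mean-adaptive thresholding
(robust to shadows and uneven illumination).  Downstream stages treat the
three variants as independent witnesses and merge their readings.

Images are ``uint8`` numpy arrays: ``(H, W)`` greyscale or ``(H, W, 3)`` RGB,
intensities in [0, 255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Canonical sharpening kernel: identity plus a 4-neighbour Laplacian.
SHARPEN_KERNEL = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=float)

#: 3×3 box blur.
BOX_BLUR_KERNEL = np.full((3, 3), 1.0 / 9.0)

#: ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])

VARIANT_TAGS = ("greyscale", "sharpened", "blurred")


def _check_image(image: np.ndarray, channels: int | None = None) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim not in (2, 3) or (image.ndim == 3 and image.shape[2] != 3):
        raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    if channels == 1 and image.ndim != 2:
        raise ValueError("expected a single-channel image")
    return image


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit greyscale with BT.601 luma weights.

    Already-greyscale input is returned unchanged.
    """
    image = _check_image(image)
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    grey = np.rint(image.astype(float) @ _LUMA)
    return np.clip(grey, 0, 255).astype(np.uint8)


def convolve_3x3(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve a greyscale image with a 3×3 kernel.

    Borders replicate the edge pixel (avoids dark halos at label edges); the
    result is rounded and clamped to [0, 255].
    """
    image = _check_image(image, channels=1)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (3, 3):
        raise ValueError(f"kernel must be 3x3, got shape {kernel.shape}")
    # correlate, not convolve: image-processing "kernel filters" slide the
    # kernel without flipping it (irrelevant for the symmetric defaults)
    out = ndimage.correlate(image.astype(float), kernel, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def adaptive_threshold(
    image: np.ndarray, block_size: int = 11, offset_c: float = 2.0
) -> np.ndarray:
    """Binarize by comparing each pixel with its local block mean.

    A pixel is foreground (255) iff its intensity exceeds the mean of the
    ``block_size``×``block_size`` neighbourhood minus ``offset_c``.  Because
    the reference is local, a smooth shadow shifts pixel and mean together
    and the classification survives.  Images smaller than the block fall
    back to a global-mean threshold.
    """
    image = _check_image(image, channels=1)
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be odd and >= 3")
    if min(image.shape) < block_size:
        logger.warning(
            "image %s smaller than block_size %d; using global mean threshold",
            image.shape,
            block_size,
        )
        local_mean = np.full(image.shape, image.mean())
    else:
        local_mean = ndimage.uniform_filter(
            image.astype(float), size=block_size, mode="nearest"
        )
    return np.where(image > local_mean - offset_c, 255, 0).astype(np.uint8)


@dataclass(frozen=True)
class VariantSet:
    """The three preprocessed variants derived from one photograph."""

    greyscale: np.ndarray
    sharpened: np.ndarray
    blurred_thresholded: np.ndarray

    def __post_init__(self) -> None:
        shape = self.greyscale.shape
        for name in ("sharpened", "blurred_thresholded"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"variant {name} shape differs from greyscale")

    def items(self):
        """Pairs of (variant tag, image), in merge precedence order."""
        return (
            ("greyscale", self.greyscale),
            ("sharpened", self.sharpened),
            ("blurred", self.blurred_thresholded),
        )


def make_variants(
    image: np.ndarray, block_size: int = 11, offset_c: float = 2.0
) -> VariantSet:
    """Produce the three OCR input variants from one photo."""
    grey = to_greyscale(image)
    sharpened = convolve_3x3(grey, SHARPEN_KERNEL)
    blurred = convolve_3x3(grey, BOX_BLUR_KERNEL)
    thresholded = adaptive_threshold(blurred, block_size=block_size, offset_c=offset_c)
    return VariantSet(grey, sharpened, thresholded)


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG label photo as an RGB or greyscale uint8 array."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an image array as PNG (used by the CLI debug flag)."""
    Image.fromarray(_check_image(image)).save(path, format="PNG")
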