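"""Blank-slide calibration, color inversion, and scalar signal extraction.

A chromogenic round image is dark-stain-on-white.  Three steps turn it into
a quantifiable bright-on-dark map:

1. ``white_balance`` — divide each channel by the blank slide's per-channel
   median, removing illumination color and gain so the unstained background
   sits at white.
2. ``invert`` — per-channel complement ``1 - c``; the literal operation the
   overlay schemes build on (stain becomes a bright signal on dark).
3. ``extract_signal`` — collapse RGB to one scalar per pixel.  Default mode
   ``inverted_luminance``: 1 minus Rec. 709 relative luminance, the direct
   scalar analog of plain inversion.  Optional mode ``deconvolution``:
   project the per-pixel optical-density vector onto the chromogen's unit
   OD direction (stain-specific, rejects gray debris), rescaled so the
   99.9th percentile maps to 1.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import SignalMap, StainedSlideImage
from .simulate import DEFAULT_CHROMOGEN_OD

logger = logging.getLogger(__name__)

#: Rec. 709 luminance weights
_LUMA = np.array([0.2126, 0.7152, 0.0722])

SIGNAL_MODES = ("inverted_luminance", "deconvolution")


def white_balance(image: StainedSlideImage) -> StainedSlideImage:
    """Calibrate against the blank slide: divide by per-channel blank medians.

    The median (not mean) makes the calibration robust to noise and debris
    on the blank scan.  Without a blank reference the image passes through
    unchanged with a warning; a zero-median blank channel is an error.
    """
    if image.blank_reference is None:
        logger.warning("no blank reference for marker %s round %d: "
                       "white balance skipped", image.marker, image.round_index)
        return image
    medians = np.median(image.blank_reference.reshape(-1, 3), axis=0)
    if np.any(medians <= 0):
        raise ValueError("blank reference has a zero-median channel")
    balanced = np.clip(image.pixels / medians[None, None, :], 0.0, 1.0)
    return image.with_pixels(balanced)


def invert(image: StainedSlideImage) -> StainedSlideImage:
    """Per-channel complement ``1 - c``: dark stain on white becomes bright
    signal on dark.  Involution: ``invert(invert(I)) == I``."""
    return image.with_pixels(1.0 - image.pixels)


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 709 relative luminance of an RGB raster."""
    return pixels @ _LUMA


def extract_signal(image: StainedSlideImage, mode: str = "inverted_luminance",
                   chromogen_od: tuple[float, float, float] = DEFAULT_CHROMOGEN_OD,
                   rescale_percentile: float = 99.9) -> SignalMap:
    """Collapse a white-balanced round image to a scalar signal map in [0, 1].

    Parameters
    ----------
    mode : {"inverted_luminance", "deconvolution"}
        ``inverted_luminance``: ``1 - luminance`` (stain-agnostic).
        ``deconvolution``: per-pixel OD vector ``-ln(c)`` projected onto the
        unit chromogen OD direction, rescaled so the ``rescale_percentile``
        maps to 1 (percentile rather than max, for robustness to hot pixels).
    """
    if mode not in SIGNAL_MODES:
        raise ValueError(f"unknown signal mode {mode!r}; choose from {SIGNAL_MODES}")
    if not np.isfinite(image.pixels).all():
        raise ValueError("image contains non-finite pixels")
    if mode == "inverted_luminance":
        values = 1.0 - luminance(image.pixels)
    else:
        od_dir = np.asarray(chromogen_od, dtype=np.float64)
        od_dir = od_dir / np.linalg.norm(od_dir)
        od = -np.log(np.clip(image.pixels, 1e-6, 1.0))
        values = od @ od_dir
        scale = np.percentile(values, rescale_percentile)
        if scale > 0:
            values = values / scale
    return SignalMap(values=np.clip(values, 0.0, 1.0), marker=image.marker,
                     pixel_size_um=image.pixel_size_um, frame="native")
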