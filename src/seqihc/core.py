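"""Shared image containers for the sequential-IHC pipeline.

A staining *series* is one physical tissue section scanned once per round,
with a different marker stained in each round.  Every round is a brightfield
RGB raster: near-white unstained background, dark red-brown chromogen
deposits where the round's marker is expressed.  Two containers flow through
the pipeline:

``StainedSlideImage``
    one round's RGB scan (channels in [0, 1]) plus its marker label, round
    index, pixel size and optional blank-slide reference scan.

``SignalMap``
    a scalar per-pixel marker signal in [0, 1], bright-on-dark, derived from
    a calibrated round image; the substrate for registration, pseudocolor
    overlays and per-cell quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


def _check_unit_range(arr: np.ndarray, what: str) -> None:
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{what} values must lie in [0, 1]")


@dataclass
class StainedSlideImage:
    """One round's brightfield RGB scan.

    Parameters
    ----------
    pixels : (H, W, 3) float array
        RGB raster, each channel in [0, 1], origin top-left, row-major.
    marker : str
        Name of the protein stained in this round (e.g. ``"GAD67"``).
    round_index : int
        1-based staining round.
    pixel_size_um : float
        Physical size of one pixel in micrometres.
    blank_reference : (H, W, 3) float array, optional
        Scan of an unstained blank slide under the same illumination,
        used for white-balance calibration.
    """

    pixels: np.ndarray
    marker: str
    round_index: int = 1
    pixel_size_um: float = 0.5
    blank_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB raster")
        _check_unit_range(self.pixels, "pixels")
        if self.blank_reference is not None:
            self.blank_reference = np.asarray(self.blank_reference, dtype=np.float64)
            if self.blank_reference.shape != self.pixels.shape:
                raise ValueError("blank_reference dimensions must match pixels")
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def with_pixels(self, pixels: np.ndarray) -> "StainedSlideImage":
        return replace(self, pixels=pixels)


@dataclass
class SignalMap:
    """Scalar bright-on-dark marker signal, one value per pixel in [0, 1]."""

    values: np.ndarray
    marker: str
    pixel_size_um: float = 0.5
    #: "native" before registration, "reference" once warped into round 1's frame
    frame: str = "native"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D raster")
        _check_unit_range(self.values, "signal values")
        if self.frame not in ("native", "reference"):
            raise ValueError("frame must be 'native' or 'reference'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, frame: str | None = None) -> "SignalMap":
        return replace(self, values=values, frame=frame or self.frame)


# ---------------------------------------------------------------------------
# raster I/O (text-free formats are fine to *write*; the deliverable carries
# no binary fixtures — images are regenerated by the simulator at run time)
# ---------------------------------------------------------------------------

def write_image(path: str | Path, pixels: np.ndarray, bitdepth: int = 16) -> None:
    """Write an RGB raster in [0, 1] as an 8- or 16-bit TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 16:
        data = np.round(arr * 65535.0).astype(np.uint16)
    elif bitdepth == 8:
        data = np.round(arr * 255.0).astype(np.uint8)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG raster back to float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    if data.dtype == np.uint8:
        return data.astype(np.float64) / 255.0
    if data.dtype == np.uint16:
        return data.astype(np.float64) / 65535.0
    return np.clip(data.astype(np.float64), 0.0, 1.0)


def write_signal_map(path: str | Path, sig: SignalMap) -> None:
    """Persist a signal map as a single-channel 16-bit TIFF."""
    data = np.round(np.clip(sig.values, 0.0, 1.0) * 65535.0).astype(np.uint16)
    tifffile.imwrite(Path(path), data)
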