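"""Overlay schemes for visualizing co-localization and differential expression.

Three compositions of registered round images, each answering a different
visual question about two or more markers:

``invert_A_over_B`` / ``invert_B_over_A``
    Invert one round and multiply it onto the other, pixel by pixel.
    A cell bright in the inverted round stays bright where the base round
    is unstained (white) — a differentially expressing cell pops out of the
    dark background — and is dimmed where the base round is stained dark —
    a co-expressing cell disappears.  Multiplicative blending is the unique
    standard blend with all three behaviours (bright-over-white bright,
    bright-over-dark dim, background dark); additive/screen blends fail the
    dimming.

``two_color`` / ``multi_pseudocolor``
    Recolor each marker's bright-on-dark signal map with a display hue and
    sum the layers (clipped).  Co-expression of a green and a red marker
    renders yellow; three markers (green, red, purple) give a full cortical
    co-expression map in one image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import SignalMap, StainedSlideImage

SCHEMES = ("invert_A_over_B", "invert_B_over_A", "two_color", "multi_pseudocolor")

#: default display colors, in assignment order
DEFAULT_COLORS = ((0.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.6, 0.0, 1.0))


@dataclass
class OverlayImage:
    """A rendered overlay plus the legend needed to read it."""

    pixels: np.ndarray
    scheme: str
    markers: tuple[str, ...]
    colors: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("overlay channels must lie in [0, 1]")

    def legend(self) -> dict:
        return {"scheme": self.scheme, "markers": list(self.markers),
                "colors": {m: list(c) for m, c in self.colors.items()}}


def superimpose_multiply(inverted: StainedSlideImage,
                         base: StainedSlideImage) -> OverlayImage:
    """Per-channel product of an inverted round and a base round.

    Bright pixels of ``inverted`` survive over white regions of ``base``
    (differential cells), are darkened over stained regions (co-localized
    cells), and the unstained background stays dark.  Commutative; output
    never exceeds either input per channel.
    """
    if inverted.shape != base.shape:
        raise ValueError("overlay inputs must share dimensions")
    return OverlayImage(pixels=inverted.pixels * base.pixels,
                        scheme="invert_A_over_B",
                        markers=(inverted.marker, base.marker))


def recolor(signal: SignalMap,
            display_color: tuple[float, float, float]) -> np.ndarray:
    """Map a scalar signal to a display hue: pixel = signal × color."""
    color = np.asarray(display_color, dtype=np.float64)
    return signal.values[..., None] * color[None, None, :]


def compose_additive(layers: Sequence[np.ndarray]) -> OverlayImage:
    """Sum recolored layers per channel, clipped to 1.

    Permutation-invariant.  Pixels where a green and a red layer are both
    near 1 render yellow — the co-expression signature.
    """
    if len(layers) == 0:
        raise ValueError("compose_additive needs at least one layer")
    total = np.zeros_like(np.asarray(layers[0], dtype=np.float64))
    for layer in layers:
        total = total + np.asarray(layer, dtype=np.float64)
    return OverlayImage(pixels=np.clip(total, 0.0, 1.0),
                        scheme="multi_pseudocolor", markers=())


def render_scheme(scheme: str, *,
                  images: Mapping[str, StainedSlideImage] | None = None,
                  signals: Mapping[str, SignalMap] | None = None,
                  markers: Sequence[str],
                  colors: Sequence[tuple[float, float, float]] = DEFAULT_COLORS,
                  ) -> OverlayImage:
    """Dispatch to one of the overlay schemes.

    ``invert_A_over_B`` / ``invert_B_over_A`` need two entries of ``images``
    (registered RGB rounds) for ``markers = (A, B)``; the color schemes need
    one ``signals`` entry per marker and assign ``colors`` in marker order.
    """
    from .stain import invert  # local import avoids a cycle at module load

    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    markers = tuple(markers)
    if scheme in ("invert_A_over_B", "invert_B_over_A"):
        if images is None or len(markers) != 2:
            raise ValueError(f"{scheme} needs two markers and their images")
        a, b = markers
        if scheme == "invert_B_over_A":
            a, b = b, a
        out = superimpose_multiply(invert(images[a]), images[b])
        out.scheme = scheme
        out.markers = markers
        return out
    if signals is None or len(markers) < 1:
        raise ValueError(f"{scheme} needs signal maps for its markers")
    if scheme == "two_color" and len(markers) != 2:
        raise ValueError("two_color needs exactly two markers")
    if len(colors) < len(markers):
        raise ValueError("need one display color per marker")
    assigned = {m: tuple(c) for m, c in zip(markers, colors)}
    layers = [recolor(signals[m], assigned[m]) for m in markers]
    out = compose_additive(layers)
    out.scheme = scheme
    out.markers = markers
    out.colors = assigned
    return out
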