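"""Stripping-completeness quality control.

Between staining rounds the previous antibody and chromogen are chemically
stripped; the wet-lab control re-applies only the secondary antibody and
chromogen and rescans — a clean slide means stripping was complete.  This
module is the computational readout of that control: the fraction of pixels
in the post-strip scan whose signal exceeds a blank-derived threshold.  A
pixel *fraction* (not a mean) matches the visual criterion — any stained
structure should fail the check, not just an average tint — and the
correlation of residual signal with the previous round's map localizes a
failure as carryover rather than debris.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SignalMap, StainedSlideImage
from .cells import robust_background
from .stain import extract_signal, white_balance


@dataclass
class QCParams:
    """Operating point of the stripping check."""

    #: threshold multiplier over background MAD
    k_mad: float = 5.0
    #: maximum tolerated fraction of above-threshold pixels
    max_residual_fraction: float = 0.001
    #: where the background estimate comes from: "self" (the post-strip
    #: scan's own robust statistics — tissue background dominates by area,
    #: so its median/MAD track the nonspecific tint) or "blank" (the blank
    #: slide scan; appropriate when the tissue carries no diffuse tint)
    background: str = "self"


@dataclass
class StrippingQC:
    residual_fraction: float
    residual_mean_signal: float
    correlation_with_previous: float | None
    threshold: float
    passed: bool
    params: QCParams

    @property
    def verdict(self) -> str:
        return "pass" if self.passed else "fail"

    def to_dict(self) -> dict:
        return {
            "residual_fraction": self.residual_fraction,
            "residual_mean_signal": self.residual_mean_signal,
            "correlation_with_previous": self.correlation_with_previous,
            "threshold": self.threshold,
            "verdict": self.verdict,
            "k_mad": self.params.k_mad,
            "max_residual_fraction": self.params.max_residual_fraction,
        }


def assess_stripping(post_strip: StainedSlideImage,
                     previous_round_map: SignalMap | None = None,
                     params: QCParams | None = None,
                     signal_mode: str = "inverted_luminance") -> StrippingQC:
    """Quantify residual stain in a post-strip, secondary-only scan.

    The threshold is background median + k·MAD, estimated by default from
    the post-strip scan itself (unstained tissue dominates the area, so the
    robust statistics track the nonspecific tint plus noise, not residual
    stain) or from the blank reference.  Verdict is pass iff the
    above-threshold pixel fraction stays below the configured maximum.
    When the previous round's signal map is given, the Pearson correlation
    between it and the residual signal is reported: high correlation pins
    the residual on incomplete stripping of that round.
    """
    params = params or QCParams()
    if post_strip.blank_reference is None:
        raise ValueError("stripping QC needs a blank reference for the "
                         "background noise estimate")
    balanced = white_balance(post_strip)
    residual = extract_signal(balanced, mode=signal_mode)
    if params.background == "blank":
        blank_img = StainedSlideImage(pixels=post_strip.blank_reference,
                                      marker="blank",
                                      round_index=post_strip.round_index,
                                      pixel_size_um=post_strip.pixel_size_um,
                                      blank_reference=post_strip.blank_reference)
        bg_sig = extract_signal(white_balance(blank_img), mode=signal_mode)
    elif params.background == "self":
        bg_sig = residual
    else:
        raise ValueError("QCParams.background must be 'self' or 'blank'")
    med, mad = robust_background(bg_sig.values)
    threshold = med + params.k_mad * mad
    above = residual.values > threshold
    frac = float(above.mean())
    mean_above = float(residual.values[above].mean()) if above.any() else 0.0
    corr = None
    if previous_round_map is not None:
        a = residual.values.ravel()
        b = previous_round_map.values.ravel()
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            corr = float(np.corrcoef(a, b)[0, 1])
    return StrippingQC(residual_fraction=frac, residual_mean_signal=mean_above,
                       correlation_with_previous=corr, threshold=threshold,
                       passed=frac < params.max_residual_fraction, params=params)
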