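"""Synthetic multi-round chromogenic IHC slide simulator with ground truth.

The simulator renders what a brightfield scanner sees after each staining
round of one virtual tissue section: a near-white background with dark
red-brown chromogen deposits wherever the round's marker is expressed.

Physical model
--------------
Stain deposition is modelled as an absorbance (optical-density) field
``A(x, y)`` built from three terms:

* a cosine-tapered disc ("soma bump") of the cell's radius, scaled by that
  cell's expression level for the round's marker — the cell-body stain;
* small puncta discs with Poisson placement — the sub-cellular "fine
  particle" clutter typical of chromogenic staining, which cell detection
  must reject;
* optionally, a fraction of the previous round's absorbance — residual
  chromogen from incomplete antibody stripping (carryover);
* a uniform diffuse term — the nonspecific tissue tint every chromogenic
  slide carries (``background_od``).

Expression levels in [0, 1] are mapped to optical density through
``stain_amplitude``: a fully expressing soma deposits a *dense* chromogen
plug (default peak OD 4 along the chromogen direction), so strong cells
render nearly opaque with a dark red rim — the regime in which inverted
superimposition visibly dims co-expressing cells, as on real slides.

Transmitted light follows Beer–Lambert per channel against a blank slide:
``RGB = illumination * exp(-A * chromogen_od)``, with a NOVA-Red-like
optical-density direction by default.  Optical blur, a per-round rigid
misalignment (rescans never land on exactly the same pixels) and clipped
additive Gaussian noise complete the rendering.

Cell populations are defined by a class table with overlapping membership
so that co-localization claims have planted ground truth — e.g. a class
positive for both GAD67 and parvalbumin alongside a GAD67-only class.

All randomness derives from a single seed through named per-round streams,
so any round can be re-rendered independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import StainedSlideImage
from .register import RigidTransform, warp

#: NOVA-Red-like chromogen optical-density direction (R, G, B).  The red
#: channel absorbs least, so the stain reads dark red-brown.  A modelling
#: choice (the chromogen's spectrum is not standardised), configurable.
DEFAULT_CHROMOGEN_OD = (0.30, 0.70, 0.65)


@dataclass(frozen=True)
class CellClass:
    """One cell population: a label, per-marker expression, expected count."""

    label: str
    expression: dict[str, float]
    expected_count: float


@dataclass
class SimulationParams:
    """Full parameter set for one simulated staining series.

    Lengths are micrometres unless the name says pixels.  Defaults model a
    0.5 µm/pixel brightfield scan of a thin (effectively planar) section
    with soma-scale cells, fine-particle clutter, and mild scanner noise.
    """

    markers: Sequence[str]
    class_table: Sequence[CellClass]
    field_width_um: float = 512.0
    field_height_um: float = 512.0
    pixel_size_um: float = 0.5
    cell_radius_um: float = 5.0
    cell_radius_sd_um: float = 0.75
    puncta_density_per_mm2: float = 2000.0
    puncta_radius_um: float = 0.5
    puncta_amplitude: tuple[float, float] = (0.3, 0.9)
    chromogen_od: tuple[float, float, float] = DEFAULT_CHROMOGEN_OD
    #: expression-to-OD multiplier: peak absorbance of a unit-expression soma
    stain_amplitude: float = 4.0
    #: diffuse nonspecific tissue absorbance (uniform tint)
    background_od: float = 0.15
    blur_sigma_um: float = 0.5
    noise_sd: float = 0.01
    #: blank-slide RGB level: lamp color/gain the white balance removes
    illumination: tuple[float, float, float] = (0.92, 0.94, 0.90)
    #: one (dx_px, dy_px, theta_deg) triple per round; None → all identity
    misalignment_per_round: Sequence[tuple[float, float, float]] | None = None
    carryover_fraction: float = 0.0
    #: minimum center-to-center distance; None → one mean soma radius.
    #: Note that at the default, neighbouring somata can overlap heavily and
    #: are then not resolvable by any detector; plant one soma *diameter*
    #: when ground-truth identity of every individual cell must be
    #: recoverable (e.g. co-localization validation scenes).
    min_spacing_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("at least one marker is required")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0.0 <= self.carryover_fraction <= 1.0:
            raise ValueError("carryover_fraction must lie in [0, 1]")
        for cls in self.class_table:
            if cls.expected_count < 0:
                raise ValueError(f"class {cls.label!r}: expected count must be >= 0")
            for m, e in cls.expression.items():
                if m not in self.markers:
                    raise ValueError(f"class {cls.label!r} references unknown marker {m!r}")
                if not 0.0 <= e <= 1.0:
                    raise ValueError(f"class {cls.label!r}: expression for {m!r} outside [0, 1]")
        if self.misalignment_per_round is not None and \
                len(self.misalignment_per_round) != len(self.markers):
            raise ValueError("misalignment_per_round must have one entry per round")

    @property
    def shape(self) -> tuple[int, int]:
        h = int(round(self.field_height_um / self.pixel_size_um))
        w = int(round(self.field_width_um / self.pixel_size_um))
        return h, w

    def transform_for_round(self, round_index: int) -> RigidTransform:
        if self.misalignment_per_round is None:
            return RigidTransform()
        dx, dy, th = self.misalignment_per_round[round_index - 1]
        return RigidTransform(dx, dy, th)


@dataclass
class GroundTruth:
    """Planted cell table plus the true per-round transforms.

    ``cells`` has one row per cell: ``cell_id, x_um, y_um, radius_um,
    class_label`` and one ``expr_<marker>`` column per marker.
    """

    cells: pd.DataFrame
    params: SimulationParams

    @property
    def transforms(self) -> list[RigidTransform]:
        return [self.params.transform_for_round(i + 1)
                for i in range(len(self.params.markers))]

    def expression(self, marker: str) -> np.ndarray:
        return self.cells[f"expr_{marker}"].to_numpy()

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def _stream(params: SimulationParams, *key: int) -> np.random.Generator:
    """Named RNG stream: deterministic, independent of call order."""
    return np.random.default_rng(np.random.SeedSequence([params.seed, *key]))


# stream keys
_PLACEMENT, _PUNCTA, _NOISE, _BLANK, _STRIP = 0, 1, 2, 3, 4


def generate_ground_truth(params: SimulationParams) -> GroundTruth:
    """Place cells of every class in the field.

    Per-class counts are Poisson around the expected count; centers are
    uniform with a minimum center-to-center distance of one mean soma
    radius.  Deterministic given the seed.

    Raises
    ------
    RuntimeError
        If the field is too small to place a class's cells at the minimum
        spacing (the error names the limiting class).
    """
    rng = _stream(params, _PLACEMENT)
    min_dist = (params.min_spacing_um if params.min_spacing_um is not None
                else params.cell_radius_um)
    placed_xy: list[tuple[float, float]] = []
    rows = []
    cell_id = 0
    for cls in params.class_table:
        n = int(rng.poisson(cls.expected_count))
        for _ in range(n):
            for attempt in range(2000):
                x = rng.uniform(0.0, params.field_width_um)
                y = rng.uniform(0.0, params.field_height_um)
                if all((x - px) ** 2 + (y - py) ** 2 >= min_dist ** 2
                       for px, py in placed_xy):
                    break
            else:
                raise RuntimeError(
                    f"field too small to place cells of class {cls.label!r} "
                    f"at minimum spacing {min_dist:g} um")
            radius = float(np.clip(
                rng.normal(params.cell_radius_um, params.cell_radius_sd_um),
                0.5 * params.cell_radius_um, 2.0 * params.cell_radius_um))
            placed_xy.append((x, y))
            row = {"cell_id": cell_id, "x_um": x, "y_um": y,
                   "radius_um": radius, "class_label": cls.label}
            for m in params.markers:
                row[f"expr_{m}"] = float(cls.expression.get(m, 0.0))
            rows.append(row)
            cell_id += 1
    columns = (["cell_id", "x_um", "y_um", "radius_um", "class_label"]
               + [f"expr_{m}" for m in params.markers])
    cells = pd.DataFrame(rows, columns=columns)
    return GroundTruth(cells=cells, params=params)


def _add_disc(acc: np.ndarray, x_px: float, y_px: float, radius_px: float,
              amplitude: float, tapered: bool) -> None:
    """Add one soma bump (cosine taper) or punctum (hard disc) in place."""
    if amplitude <= 0 or radius_px <= 0:
        return
    h, w = acc.shape
    r0 = max(int(np.floor(y_px - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(y_px + radius_px)) + 2, h)
    c0 = max(int(np.floor(x_px - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(x_px + radius_px)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    r = np.hypot(xx + 0.5 - x_px, yy + 0.5 - y_px)
    if tapered:
        kern = np.where(r < radius_px,
                        0.5 * (1.0 + np.cos(np.pi * np.minimum(r / radius_px, 1.0))),
                        0.0)
    else:
        kern = (r < radius_px).astype(np.float64)
    acc[r0:r1, c0:c1] += amplitude * kern


def soma_absorbance(gt: GroundTruth, marker: str) -> np.ndarray:
    """Absorbance contributed by cell somata for one marker (ground-truth frame)."""
    params = gt.params
    if marker not in params.markers:
        raise ValueError(f"unknown marker {marker!r}")
    acc = np.zeros(params.shape, dtype=np.float64)
    px = params.pixel_size_um
    expr = gt.expression(marker)
    for (x, y, radius), e in zip(
            gt.cells[["x_um", "y_um", "radius_um"]].to_numpy(), expr):
        _add_disc(acc, x / px, y / px, radius / px, e, tapered=True)
    return acc


def _puncta_absorbance(params: SimulationParams, round_index: int) -> np.ndarray:
    """Fine-particle clutter for one round (independent Poisson placement)."""
    acc = np.zeros(params.shape, dtype=np.float64)
    area_mm2 = params.field_width_um * params.field_height_um * 1e-6
    n = _stream(params, _PUNCTA, round_index).poisson(
        params.puncta_density_per_mm2 * area_mm2)
    if n == 0:
        return acc
    rng = _stream(params, _PUNCTA, round_index, 1)
    xs = rng.uniform(0.0, params.field_width_um, n) / params.pixel_size_um
    ys = rng.uniform(0.0, params.field_height_um, n) / params.pixel_size_um
    amps = rng.uniform(*params.puncta_amplitude, n)
    r_px = params.puncta_radius_um / params.pixel_size_um
    for x, y, a in zip(xs, ys, amps):
        _add_disc(acc, x, y, r_px, a, tapered=False)
    return acc


def round_absorbance(gt: GroundTruth, marker: str,
                     prev_absorbance: np.ndarray | None = None) -> np.ndarray:
    """Total absorbance field for one round in the ground-truth frame.

    ``stain_amplitude * (soma + puncta) + background_od
    + carryover_fraction * previous round's absorbance``.
    """
    params = gt.params
    round_index = list(params.markers).index(marker) + 1
    acc = soma_absorbance(gt, marker)
    acc += _puncta_absorbance(params, round_index)
    acc *= params.stain_amplitude
    acc += params.background_od
    if prev_absorbance is not None and params.carryover_fraction > 0:
        acc += params.carryover_fraction * prev_absorbance
    return acc


def _transmit(absorbance: np.ndarray, params: SimulationParams) -> np.ndarray:
    od = np.asarray(params.chromogen_od, dtype=np.float64)
    illum = np.asarray(params.illumination, dtype=np.float64)
    return illum[None, None, :] * np.exp(-absorbance[..., None] * od[None, None, :])


def _finish(rgb: np.ndarray, params: SimulationParams, t: RigidTransform,
            noise_rng: np.random.Generator) -> np.ndarray:
    if params.blur_sigma_um > 0:
        sigma_px = params.blur_sigma_um / params.pixel_size_um
        rgb = np.stack([ndimage.gaussian_filter(rgb[..., c], sigma_px)
                        for c in range(3)], axis=-1)
    if not t.is_identity:
        # outside-field fill is the blank-slide level per channel
        rgb = np.stack([warp(rgb[..., c], t, fill=params.illumination[c])
                        for c in range(3)], axis=-1)
    if params.noise_sd > 0:
        rgb = rgb + noise_rng.normal(0.0, params.noise_sd, rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


def _blank_reference(params: SimulationParams, round_index: int) -> np.ndarray:
    illum = np.asarray(params.illumination, dtype=np.float64)
    rgb = np.broadcast_to(illum, (*params.shape, 3)).copy()
    if params.noise_sd > 0:
        rng = _stream(params, _BLANK, round_index)
        rgb = rgb + rng.normal(0.0, params.noise_sd, rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


def render_round(gt: GroundTruth, marker: str,
                 prev_absorbance: np.ndarray | None = None) -> StainedSlideImage:
    """Render one round's brightfield scan.

    Beer–Lambert transmittance of the round's absorbance field, then
    optical blur, the round's true rigid misalignment, and clipped additive
    noise.  The blank reference is rendered with zero absorbance plus its
    own noise draw.
    """
    params = gt.params
    if marker not in params.markers:
        raise ValueError(f"unknown marker {marker!r}")
    round_index = list(params.markers).index(marker) + 1
    absorbance = round_absorbance(gt, marker, prev_absorbance)
    rgb = _finish(_transmit(absorbance, params), params,
                  params.transform_for_round(round_index),
                  _stream(params, _NOISE, round_index))
    return StainedSlideImage(pixels=rgb, marker=marker, round_index=round_index,
                             pixel_size_um=params.pixel_size_um,
                             blank_reference=_blank_reference(params, round_index))


def render_series(gt: GroundTruth) -> list[StainedSlideImage]:
    """Render all rounds in order, chaining carryover between rounds."""
    params = gt.params
    images = []
    prev: np.ndarray | None = None
    for marker in params.markers:
        absorbance = round_absorbance(gt, marker, prev)
        round_index = list(params.markers).index(marker) + 1
        rgb = _finish(_transmit(absorbance, params), params,
                      params.transform_for_round(round_index),
                      _stream(params, _NOISE, round_index))
        images.append(StainedSlideImage(
            pixels=rgb, marker=marker, round_index=round_index,
            pixel_size_um=params.pixel_size_um,
            blank_reference=_blank_reference(params, round_index)))
        prev = absorbance
    return images


def render_post_strip(gt: GroundTruth, after_marker: str) -> StainedSlideImage:
    """Render the stripping-completeness control scan taken after a round.

    Models the secondary-antibody-only restain: absorbance is the diffuse
    nonspecific tint plus the carryover fraction of the stripped round's
    field.  With complete stripping (carryover 0) the scan shows tissue
    tint and noise only — the wet-lab "no red stain observed" outcome.
    """
    params = gt.params
    if after_marker not in params.markers:
        raise ValueError(f"unknown marker {after_marker!r}")
    idx = list(params.markers).index(after_marker) + 1
    prev: np.ndarray | None = None
    for marker in list(params.markers)[:idx]:
        prev = round_absorbance(gt, marker, prev)
    residual = params.background_od + params.carryover_fraction * prev
    rgb = _finish(_transmit(residual, params), params, RigidTransform(),
                  _stream(params, _STRIP, idx))
    return StainedSlideImage(pixels=rgb, marker=f"post-strip-{after_marker}",
                             round_index=idx, pixel_size_um=params.pixel_size_um,
                             blank_reference=_blank_reference(params, idx))
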