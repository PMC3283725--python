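"""Cell detection, cross-marker merging, classification, and quantification.

The visual overlays say *where* to look; this module does the system-wide
statistics.  Per marker, soma-scale objects are detected in the registered
signal map (a size filter rejects the sub-cellular "fine particle" puncta
that chromogenic staining scatters everywhere).  Detections from all
markers are merged into one candidate-cell list, and each candidate is
quantified by disc sampling on every marker's map — so a cell detected only
in GAD67 still gets a parvalbumin reading, and "no or little parvalbumin"
is a measured value rather than a missed detection.  Positivity calls use
robust background statistics (median + k·MAD); relative expression
normalizes each positive cell's disc signal by the mean over all cells
positive for that marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import SignalMap


@dataclass
class DetectionParams:
    """Knobs for detection, merging and positivity calls (lengths in µm)."""

    soma_radius_um: float = 5.0
    #: positivity/detection threshold = background median + k_mad * MAD
    k_mad: float = 5.0
    #: fixed detection threshold overriding the robust one, if set
    fixed_threshold: float | None = None
    #: soma-area band: components outside discs of these radii are rejected
    min_radius_um: float = 2.5
    max_radius_um: float = 10.0
    merge_radius_um: float = 5.0
    #: disc radius for per-cell quantification; defaults to soma_radius_um
    disc_radius_um: float | None = None

    @property
    def quant_radius_um(self) -> float:
        return self.disc_radius_um if self.disc_radius_um is not None \
            else self.soma_radius_um


@dataclass
class CellDetection:
    """One soma-scale object found in a single marker's signal map."""

    x_px: float
    y_px: float
    area_px: int
    mean_signal: float
    marker: str


@dataclass
class CellRecord:
    """One candidate cell quantified across every marker."""

    record_id: int
    x_um: float
    y_um: float
    mean_signal: dict[str, float]
    positive: dict[str, bool]
    class_label: str
    relative_expression: dict[str, float] = field(default_factory=dict)


@dataclass
class ColocReport:
    """System-wide counts, conditional co-expression fractions, and QC."""

    n_cells: int
    class_counts: dict[str, int]
    marker_totals: dict[str, int]
    #: ordered-pair fractions: of X-positive cells, share also Y-positive
    conditional_fractions: dict[str, float | None]
    thresholds: dict[str, float]
    parameters: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "class_counts": self.class_counts,
            "marker_totals": self.marker_totals,
            "conditional_fractions": self.conditional_fractions,
            "thresholds": self.thresholds,
            "parameters": self.parameters,
            "qc": self.qc,
        }


def robust_background(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD of a map; with sparse staining these track background."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def detection_threshold(signal: SignalMap, params: DetectionParams) -> float:
    if params.fixed_threshold is not None:
        return params.fixed_threshold
    med, mad = robust_background(signal.values)
    return med + params.k_mad * mad


def detect_cells(signal: SignalMap, params: DetectionParams | None = None
                 ) -> list[CellDetection]:
    """Find soma-scale bright objects in one marker's signal map.

    Gaussian smoothing at half the nominal soma radius, a robust threshold,
    watershed splitting of touching somata seeded at local maxima, then the
    puncta filter: components whose *stained area* — pixels above threshold
    on the unsmoothed map — falls outside the soma-area band are discarded.
    Measuring size on the raw map matters: smoothing (needed for clean
    segmentation) inflates a chance cluster of fine particles to soma-scale
    mask area, but its genuinely stained pixels remain a scatter of dots.
    Centroids are intensity-weighted.  An all-zero map yields an empty list.
    """
    params = params or DetectionParams()
    px = signal.pixel_size_um
    soma_r_px = params.soma_radius_um / px
    smoothed = ndimage.gaussian_filter(signal.values, 0.5 * soma_r_px)
    thr = detection_threshold(signal, params)
    mask = smoothed > thr
    if not mask.any():
        return []
    min_sep = max(1, int(round(0.7 * soma_r_px)))
    peaks = peak_local_max(smoothed, min_distance=min_sep, threshold_abs=thr,
                           exclude_border=False)
    if len(peaks) == 0:
        return []
    seeds = np.zeros(smoothed.shape, dtype=np.int32)
    seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers=seeds, mask=mask)
    a_min = np.pi * (params.min_radius_um / px) ** 2
    a_max = np.pi * (params.max_radius_um / px) ** 2
    raw_mask = signal.values > thr
    out = []
    for region in regionprops(labels, intensity_image=signal.values):
        stained_area = int(raw_mask[tuple(region.coords.T)].sum())
        if not a_min <= stained_area <= a_max:
            continue
        cy, cx = region.centroid_weighted
        out.append(CellDetection(x_px=float(cx), y_px=float(cy),
                                 area_px=stained_area,
                                 mean_signal=float(region.intensity_mean),
                                 marker=signal.marker))
    return out


def merge_detections(per_marker: Mapping[str, Sequence[CellDetection]],
                     merge_radius_um: float = 5.0,
                     pixel_size_um: float = 0.5) -> np.ndarray:
    """Merge per-marker detections into one candidate-cell centroid list.

    Single-linkage clustering at ``merge_radius_um`` over the union of all
    detections; each cluster contributes the mean of its members.  Returns
    an ``(n, 2)`` array of (x_um, y_um) sorted by y then x — deterministic
    regardless of marker order.
    """
    pts = []
    for dets in per_marker.values():
        for d in dets:
            pts.append(((d.x_px + 0.5) * pixel_size_um,
                        (d.y_px + 0.5) * pixel_size_um))
    if not pts:
        return np.empty((0, 2))
    pts = np.asarray(pts)
    parent = np.arange(len(pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(merge_radius_um):
        parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(len(pts))])
    centroids = np.array([pts[roots == r].mean(axis=0) for r in np.unique(roots)])
    order = np.lexsort((centroids[:, 0], centroids[:, 1]))
    return centroids[order]


def _disc_mean(values: np.ndarray, x_um: float, y_um: float,
               radius_um: float, pixel_size_um: float) -> float:
    h, w = values.shape
    x_px, y_px = x_um / pixel_size_um, y_um / pixel_size_um
    r_px = radius_um / pixel_size_um
    r0, r1 = int(np.floor(y_px - r_px)), int(np.ceil(y_px + r_px)) + 1
    c0, c1 = int(np.floor(x_px - r_px)), int(np.ceil(x_px + r_px)) + 1
    if r1 <= 0 or c1 <= 0 or r0 >= h or c0 >= w:
        raise ValueError("quantification disc lies fully outside the raster")
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = np.hypot(xx + 0.5 - x_px, yy + 0.5 - y_px) <= r_px
    if not inside.any():
        raise ValueError("quantification disc lies fully outside the raster")
    return float(values[r0:r1, c0:c1][inside].mean())


def class_label(positive: Mapping[str, bool], markers: Sequence[str]) -> str:
    pos = [m for m in markers if positive.get(m, False)]
    if not pos:
        return "none"
    if len(pos) == 1:
        return f"{pos[0]}-only"
    return "+".join(pos)


def quantify_cell(record_id: int, centroid_um: tuple[float, float],
                  signal_maps: Mapping[str, SignalMap],
                  thresholds: Mapping[str, float],
                  disc_radius_um: float,
                  markers: Sequence[str],
                  sample_points: Mapping[str, tuple[float, float]] | None = None
                  ) -> CellRecord:
    """Disc-sample every marker's map at one centroid and call positivity.

    ``sample_points`` optionally gives a per-marker coordinate (native-frame
    position of the same cell), so maps never need resampling; by default
    every map is sampled at the centroid itself.
    """
    x_um, y_um = centroid_um
    means, flags = {}, {}
    for m in markers:
        sig = signal_maps[m]
        sx, sy = sample_points[m] if sample_points is not None else (x_um, y_um)
        means[m] = _disc_mean(sig.values, sx, sy, disc_radius_um,
                              sig.pixel_size_um)
        flags[m] = means[m] >= thresholds[m]
    return CellRecord(record_id=record_id, x_um=float(x_um), y_um=float(y_um),
                      mean_signal=means, positive=flags,
                      class_label=class_label(flags, markers))


def build_cell_records(centroids_um: np.ndarray,
                       signal_maps: Mapping[str, SignalMap],
                       params: DetectionParams | None = None,
                       markers: Sequence[str] | None = None,
                       transforms: Mapping[str, "object"] | None = None
                       ) -> tuple[list[CellRecord], dict[str, float]]:
    """Quantify all candidate cells, then fill in relative expression.

    Relative expression of marker *m* in a cell = its background-subtracted
    disc mean divided by the mean background-subtracted disc signal over all
    cells positive for *m* (second pass).  A value of 1 means "average
    positive cell"; subtracting the map's background median first makes the
    ratio track the underlying expression level rather than the nonspecific
    tissue tint.

    When ``transforms`` maps markers to the rigid transform that aligns the
    marker's *native* map into the reference frame, each ``signal_maps[m]``
    is taken to be native and is sampled at the inverse-transformed centroid
    — disc quantification then never touches resampled pixels.
    """
    params = params or DetectionParams()
    markers = list(markers) if markers is not None else list(signal_maps)
    thresholds = {m: detection_threshold(signal_maps[m], params) for m in markers}

    def sample_points(c_um):
        if transforms is None:
            return None
        from .register import transform_points_um

        pts = {}
        for m in markers:
            sig = signal_maps[m]
            t = transforms[m]
            pts[m] = tuple(transform_points_um(
                np.asarray(c_um), t.inverse(), sig.shape, sig.pixel_size_um)[0])
        return pts

    records = []
    for c in (np.atleast_2d(centroids_um) if len(centroids_um) else []):
        try:
            rec = quantify_cell(len(records), tuple(c), signal_maps, thresholds,
                                params.quant_radius_um, markers,
                                sample_points(c))
        except ValueError:
            # a border cell whose disc left the raster in some round cannot
            # be quantified consistently across markers; skip it
            continue
        records.append(rec)
    for m in markers:
        bg_med = float(np.median(signal_maps[m].values))
        pos_means = [r.mean_signal[m] - bg_med for r in records if r.positive[m]]
        ref = float(np.mean(pos_means)) if pos_means else float("nan")
        for r in records:
            r.relative_expression[m] = ((r.mean_signal[m] - bg_med) / ref
                                        if ref and np.isfinite(ref) and ref > 0
                                        else float("nan"))
    return records, thresholds


def records_to_frame(records: Sequence[CellRecord],
                     markers: Sequence[str]) -> pd.DataFrame:
    """Flatten records to the cell table written as TSV."""
    rows = []
    for r in records:
        row = {"record_id": r.record_id, "x_um": r.x_um, "y_um": r.y_um}
        for m in markers:
            row[f"signal_{m}"] = r.mean_signal[m]
            row[f"positive_{m}"] = int(r.positive[m])
            row[f"rel_expr_{m}"] = r.relative_expression.get(m, float("nan"))
        row["class_label"] = r.class_label
        rows.append(row)
    cols = (["record_id", "x_um", "y_um"]
            + [f"{p}_{m}" for m in markers
               for p in ("signal", "positive", "rel_expr")]
            + ["class_label"])
    return pd.DataFrame(rows, columns=cols)


def summarize(records: Sequence[CellRecord], markers: Sequence[str],
              thresholds: Mapping[str, float] | None = None,
              parameters: dict | None = None, qc: dict | None = None
              ) -> ColocReport:
    """Counts per class and conditional co-expression fractions.

    For every ordered marker pair (X, Y): the fraction of X-positive cells
    that are also Y-positive — e.g. ``"PV->GAD67" = 1.0`` means every
    PV-positive cell expresses GAD67.  Undefined fractions (no X-positive
    cells) are reported as None.
    """
    class_counts: dict[str, int] = {}
    for r in records:
        class_counts[r.class_label] = class_counts.get(r.class_label, 0) + 1
    marker_totals = {m: sum(r.positive[m] for r in records) for m in markers}
    conditional: dict[str, float | None] = {}
    for x in markers:
        for y in markers:
            if x == y:
                continue
            nx = marker_totals[x]
            both = sum(r.positive[x] and r.positive[y] for r in records)
            conditional[f"{x}->{y}"] = (both / nx) if nx else None
    return ColocReport(n_cells=len(records), class_counts=class_counts,
                       marker_totals=marker_totals,
                       conditional_fractions=conditional,
                       thresholds=dict(thresholds or {}),
                       parameters=parameters or {}, qc=qc or {})


def match_centroids(detected_um: np.ndarray, true_um: np.ndarray,
                    radius_um: float = 5.0) -> tuple[int, int, int]:
    """Greedy nearest-first matching of detections to planted cells.

    Returns (matched, n_detected, n_true) for recall/precision bookkeeping.
    """
    detected_um = np.atleast_2d(detected_um) if len(detected_um) else np.empty((0, 2))
    true_um = np.atleast_2d(true_um) if len(true_um) else np.empty((0, 2))
    if len(detected_um) == 0 or len(true_um) == 0:
        return 0, len(detected_um), len(true_um)
    d = np.linalg.norm(detected_um[:, None, :] - true_um[None, :, :], axis=2)
    matched = 0
    used_d, used_t = set(), set()
    pairs = np.argwhere(d <= radius_um)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    for i, j in pairs[order]:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return matched, len(detected_um), len(true_um)
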