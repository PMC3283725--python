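# Methods

This note documents the models, parameter choices, and numerical decisions
behind `seqihc`, and what the simulator-based validation does and does not
establish about real slides.

## Imaging model and simulator

One virtual tissue section is imaged once per staining round. Each round's
scan is modelled in absorbance (optical-density) space and converted to
brightfield RGB with Beer–Lambert transmittance:

```
A_r(x, y) = stain_amplitude · [ Σ_cells expr_r(cell) · soma(x, y)
                                + puncta_r(x, y) ]
            + background_od
            + carryover_fraction · A_{r−1}(x, y)

RGB_r = illumination · exp(−A_r · chromogen_od)
```

followed by Gaussian optical blur, the round's rigid misalignment
(inverse-mapped bilinear resampling, blank-level fill outside the field),
and clipped additive Gaussian noise. The blank reference is rendered with
zero absorbance plus its own noise draw.

Component choices:

- **Soma kernel** — a cosine-tapered disc of the cell's radius with unit
  peak, so a cell's expression level *is* its peak absorbance before the
  amplitude scaling. Puncta are small hard discs with independent Poisson
  placement per round; they model the sub-cellular "fine particle" clutter
  chromogenic staining produces and exist so the detection stage has
  something realistic to reject.
- **Chromogen OD direction** `(0.30, 0.70, 0.65)` — a NOVA-Red-like
  red-transmitting direction. The chromogen is not spectrally standardised;
  the direction is a modelling choice and configurable.
- **`stain_amplitude` (default 4.0)** — maps a unit expression level to a
  peak soma OD of 4 along the chromogen direction, i.e. transmittance
  ≈ (0.29, 0.06, 0.07): a dense, nearly opaque deposit with a dark red rim.
  This is deliberate: the defining visual phenomenon of the inverted
  overlay — co-expressing cells dimming into the dark background — only
  occurs when stained somata are close to opaque. With a unit-amplitude
  stain the per-channel product `x·(1−x)` of a stain with its own inverse
  peaks at 0.25 and co-stained cells would remain clearly visible, which is
  not what stained slides show.
- **`background_od` (default 0.15)** — a uniform diffuse tissue tint
  (nonspecific chromogen binding). It gives the overlay background its
  realistic non-zero level, and it is what the stripping QC and the
  relative-expression normalisation must be robust against.
- **Geometry** — 0.5 µm/pixel by default; a 5 µm-thick section is treated
  as a single plane (no z-structure). Mean soma radius 5 ± 0.75 µm.
  Placement is uniform with a minimum center-to-center spacing of one mean
  soma radius by default. At that spacing neighbouring somata may overlap
  almost completely; validation scenes whose claims require every planted
  cell to be individually recoverable (co-localization fractions) plant at
  one soma *diameter* instead (`min_spacing_um = 10`), which corresponds to
  touching-but-resolvable cortical packing.
- **Carryover** is additive in absorbance before exponentiation, modelling
  residual chromogen/antibody from incomplete stripping; it compounds
  across rounds. The post-strip control scan is rendered as tissue tint
  plus the carryover of the stripped round only (the secondary-only
  restain).
- **Randomness** — every stochastic component draws from a named stream
  derived from the single simulation seed and the round index, so any round
  can be re-rendered in isolation bit-identically.

What the simulator does **not** emulate: tissue deformation between rounds
(rigid jitter only), spatially structured illumination, scanner compression
artifacts, cell-shape irregularity, or marker-dependent subcellular
localisation. Tests passing on this simulator therefore establish the
correctness of the pipeline's algebra, geometry and statistics under the
stated staining model — not robustness to deformation or segmentation of
irregular morphologies.

## Calibration and signal extraction

White balance divides each channel by the blank scan's per-channel median
(median for robustness to blank noise/debris) and clips to [0, 1]. The
scalar signal is `1 − Rec. 709 luminance` by default — the direct scalar
analog of the whole-image RGB inversion used for the overlays. A
stain-deconvolution mode (per-pixel OD vector projected onto the unit
chromogen direction, rescaled so the 99.9th percentile maps to 1) is
provided for quantification: it is linear in absorbance, which the
inverted-luminance signal is not. The percentile rescale trades a small
amount of top-end clipping for robustness to hot pixels; analyses that
must avoid any saturation can set the rescale percentile to 100.

## Registration

Rounds are rescans of one physical slide, so alignment is rigid (translation
+ rotation about the raster center). Translation comes from phase
correlation with subpixel upsampling; rotation from a coarse (±3°, 0.25°)
then fine (0.05°) search maximising the phase-correlation match. Because
the rotation score is a global property, both sweeps run on block-averaged
rasters (~512 px coarse, ~1024 px fine) with the final translation
estimated at full resolution — on simulated 1024² maps at default noise
this recovers planted transforms to ≤ 0.1 px and ≤ 0.05°, in about 3 s per
round. Registration uses signal maps rather than RGB so shared tissue
structure, not round-specific stain color, drives the alignment. Rounds
are registered to round 1 by default; a chained (consecutive-round)
strategy is available for series whose late rounds share little structure
with round 1.

## Detection and quantification

Per marker: Gaussian smoothing at half the nominal soma radius, threshold
at `background median + k·MAD` (k = 5; the median/MAD of the whole map
track the background because staining is sparse), watershed splitting
seeded at local maxima, and a soma-area band filter (discs of radius
2.5–10 µm). The band is evaluated on the *stained area* — pixels above
threshold in the unsmoothed map — because smoothing inflates a chance
puncta cluster to soma-scale mask area while its genuinely stained pixels
remain a scatter of dots; this distinction is what drives puncta-only
fields to zero detections.

Detection and disc sampling run on each round's **native** map; centroids
are carried between frames through the estimated rigid transforms.
Resampling an image before detection smears puncta and can push chance
clusters over the soma-area minimum, so no detected or quantified pixel is
ever interpolated. Warped maps are still produced for overlays and saved
artifacts.

Detections from all markers are merged by single-linkage clustering at
5 µm with deterministic (y, x) ordering, and every merged centroid is disc-
sampled on every marker's map — a cell detected in only one round still
gets a continuous reading for all markers, so "little or no expression" is
a measurement, not a missed detection. Positivity uses the same robust
threshold; relative expression is the background-subtracted disc mean
divided by the mean background-subtracted disc signal over all cells
positive for that marker. Subtracting the background median first is
essential with a diffuse tissue tint: the raw ratio of two cells at a 2:1
expression ratio is compressed toward 1 by the common tint, while the
subtracted ratio recovers 2:1 to within a few percent (the residual bias
comes from blur acting in transmittance rather than OD space).

Cells whose quantification disc leaves the raster in any round are dropped
rather than partially quantified.

## Stripping QC

The residual of a post-strip, secondary-only scan is summarised as the
fraction of pixels above `median + k·MAD` — a pixel *fraction* rather than
a mean because the wet-lab criterion ("no stain observed") is sensitive to
any stained structure, not average tint. The background statistics come
from the post-strip scan itself by default (unstained tissue dominates the
area, so its median/MAD reflect tint plus noise; blank-slide statistics
would flag the whole tinted tissue as residual); a blank-based mode exists
for tint-free material. The default operating point `f_max = 0.001` sits
above the ~4·10⁻⁴ false-positive rate of Gaussian noise at k = 5 while
failing any visible carryover; it is exposed in the configuration and
recorded in the report. The Pearson correlation between the residual map
and the previous round's signal localises a failure as carryover.

## Pipeline and determinism

`run_pipeline` executes white balance → signal extraction → registration
(round 1 as reference) → requested overlays → detection/merging/
quantification → stripping QC, writing overlays, the per-cell TSV, the
JSON report (including estimated transforms, thresholds and QC verdicts)
and a log. All computation is deterministic given the configuration seed;
rerunning reproduces the cell table bit-identically, and re-analysing the
simulator's 16-bit TIFF output from disk reproduces the in-memory class
counts and fractions (quantisation at 16 bits is ~1.5·10⁻⁵, far below any
threshold margin).

## Validation scene sizes

The test suite and `scripts/acceptance.py` use fields of 400–1000 µm at
0.5 µm/pixel (800²–2000² pixels) with 50–500 planted cells: large enough
for stable robust-background statistics and ±4-percentage-point class
fractions at n ≈ 500, while a full run stays around a minute on one CPU.

## Known limitations

- Rigid-only registration; real sections that deform between rounds need
  elastic alignment this package does not provide.
- Overlapping somata closer than ~one radius are merged by any
  segmentation; co-expression read at such pairs is a resolution artifact.
- The positivity threshold is a global per-map constant; strong spatial
  variation in background staining would require local background models.
- One chromogen per round: no within-round multi-stain unmixing.
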