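# Methods

## Input model

A batch is a main folder with one immediate subfolder per imaged field; each
subfolder holds unmerged single-channel grayscale images whose filename stems
are consistent across the batch (e.g. `Laminin.tif`, `DAPI.tif`, `RFP.tif`).
TIFF is preferred because it is lossless; PNG/JPEG are accepted with a
warning. RGB exports collapse to gray by the per-pixel maximum over color
planes (a fluorescence stain lives in one plane; max is robust to export
variations), multi-page TIFFs use page 0. The effective pixel size
(camera pixel pitch / total magnification, μm per pixel) is a single global
batch parameter; its square converts pixel counts to μm². All channels of a
field must share pixel dimensions; a mismatch is a per-field error, and a
failing field never aborts the batch.

## Segmentation

1. Normalize the boundary channel to [0, 1] and smooth with a Gaussian
   (σ = 0.5 px default). The light blur bleeds ridge intensity into
   small staining gaps, which helps the threshold close them; anything
   stronger (median filtering, local histogram equalization) was found to
   thin the few-pixel-wide boundary ridge faster than it removes noise,
   producing spurious fiber merges, so the quality switch deliberately does
   not add denoising stages.
2. Threshold by Otsu. If the threshold classifies <1% or >99% of pixels as
   boundary the histogram is effectively unimodal and a fixed 90th-percentile
   quantile is used instead, with a warning.
3. Morphologically close the boundary mask with a disk. The radius is the
   `low`/`high` image-quality switch: radius 2 px (`high`) or 3 px (`low`),
   bridging staining gaps up to roughly the radius. Larger gaps can fuse
   neighbouring fibers; fusing only ever lowers the fiber count.
4. Label the 4-connected components of the non-boundary pixels (4-adjacency
   prevents diagonal leakage across one-pixel lines) and fill interior
   holes, which absorbs unstained intracellular patches.
5. Grow each label halfway into the boundary band (`expand_labels`, distance
   = the band's median half-width estimated from its skeleton and distance
   transform). The rationale: laminin stains the extracellular basal lamina
   shared by adjacent fibers, so a fiber's cross-section extends to the
   middle of the stained band; stopping at the stain's edge biases CSA low
   by about perimeter × band-width / 2 (over 10% for a 3 px band on a
   2000 μm² fiber at 1 μm/px). Setting `expand_into_boundary=False`
   restores strict "label 0 = boundary" behaviour.

The pipeline keeps two aligned label maps with a shared numbering: the
*measured* map (expanded) for CSA, and the *interior* map (stain-free
cytoplasm) for nucleus geometry and MFI, since boundary-band pixels carry
extracellular signal. Regions touching the image edge are retained — field
counts are per visible area — and are gated only by the size filter; their
CSA is the visible area, a documented caveat. An optional distance-transform
watershed can split merged candidates; it is off by default. Everything is
deterministic: same image and parameters, bit-identical labels.

## Morphometry

CSA = area_px × (μm/px)², exactly covariant in the squared pixel size. The
size window is inclusive at both ends (the least surprising reading of a
min/max filter); defaults are 200–3000 μm², appropriate for regenerating
muscle at 7 days post-injury at ~1 μm/px, with 200–4800 μm² the usual
choice for uninjured mouse TA. Survivors are renumbered 1..N by raster order
of each region's topmost-then-leftmost pixel so the overlay numbering is
visually predictable; rejected candidates are logged with their reason.
Centroids are mean pixel coordinates, (row, col), 0-based.

## Central nucleation

Nuclei are detected on the nuclear channel by Gaussian smoothing (σ = 1),
Otsu thresholding, connected components and a minimum-area filter
(default 4 px). A fiber is called centrally nucleated when at least one
nucleus *centroid* (centroid membership avoids double counting a nucleus
that overlaps two fibers) lies in the fiber's central zone: pixels whose
distance to the fiber edge exceeds `(1 − central_fraction) × √(area/π)`.
The rule is scale-free, works for non-convex fibers and has one tunable,
`central_fraction` (default 0.5); enlarging it grows the central zone
monotonically, so calls can only flip FALSE→TRUE. This geometric criterion
is this package's own operationalization of "central"; other tools may draw
the line differently.

## MFI

The arithmetic mean of the raw intensity channel over the fiber's interior
mask, in the channel's native arbitrary units. No background subtraction,
flat-field correction or normalization is applied, so values are comparable
only within an acquisition setting.

## Synthetic ground truth

Scenes emulate transverse muscle fields. Per-fiber target areas are drawn
from a lognormal (mean 2000 μm², log-σ 0.30, truncated to 200–4800 μm² —
real CSA histograms are right-skewed, and the defaults reflect uninjured
mouse TA at 1 μm/px); one seed per fiber is dart-thrown with separation
proportional to target radius, and the field is tessellated by their
bounded Voronoi diagram (mirror-reflection construction, cells clipped
exactly to the frame). Two Lloyd relaxation steps (default) round the cells
the way healthy fibers are; extra steps are applied, and placement retried,
until realized cell areas fall inside the truncation range, since an
unweighted Voronoi diagram cannot hit prescribed per-cell areas exactly.
The realized polygon areas — recorded exactly via their vertices, with
shoelace areas and perimeters — are the ground truth; the mean realized
area equals the target mean by construction (the field is sized as
√(Σ target areas)), while individual areas only loosely track their
targets.

The boundary channel renders a bright band (default 3 px wide, 200 AU)
centred on inter-cell edges; the frame itself is not a boundary, so edge
fibers appear clipped as in real fields. Staining dropout is modelled by
punching isolated disk-shaped holes (default radius 1 px, i.e. ~2 px
openings) through the band until the requested fraction of band pixels is
deleted; punch centres are kept apart so gap size stays controlled by the
punch radius. The nuclear channel plants one disk (radius 3 px) per
assigned nucleus: `central` nuclei at the fiber's most interior pixel,
`peripheral` nuclei ~1 px inside the boundary band; the central/peripheral
assignment is an exact rounded count of the requested fractions. The
intensity channel fills every cell at its known mean (uniform 50–200 AU
unless given explicitly). Gaussian noise of a single σ is added to all
channels and clipped at zero; channels are written as float32 TIFFs so
means survive exactly. One seeded generator drives everything;
`write_fixture_batch` emits the on-disk folder layout the pipeline consumes,
plus a tab-separated truth table recording the seed.

What the generator does *not* emulate: uneven illumination, out-of-focus
blur, stain cross-bleed, interstitial cells and freezing artifacts, fiber
splitting/branching, and multiple nuclei per fiber. Passing the synthetic
benchmarks therefore demonstrates the geometry and bookkeeping of the
pipeline — boundary-gap robustness, area/nucleation/intensity recovery —
not performance on degraded real histology, which still warrants spot
checks against manual counts (the validation module exists for exactly
that comparison).

## Agreement statistics

Percent accuracy of any summary quantity is
`(1 − |manual − automated| / manual) × 100`, symmetric in the direction of
the disagreement. Object-level agreement first matches objects one-to-one:
greedy, highest mask-IoU first (minimum IoU 0.1), with a nearest-centroid
fallback (radius 15 px) for objects lacking masks; greedy matching equals
the exhaustive optimum whenever overlaps are unambiguous (IoU > 0.5).
Unmatched detections are false positives, unmatched references false
negatives; both are reported as a percentage of the *reference* (manual)
count, a convention stated here because the denominator is otherwise
ambiguous. Regression is ordinary least squares with r² the squared Pearson
correlation. Histograms use left-closed right-open bins anchored at 0
(CSA and MFI are nonnegative); counts are always conserved.

## Outputs

Per processed image: `final.tif` in the image's folder (boundary backdrop,
green fiber outlines, yellow fiber numbers drawn with a built-in bitmap
font at each centroid — no font dependencies, so overlays are byte-stable),
and in `<main>/Results/`: `<folder>_CSA.csv` (one comma-separated line of
CSAs in fiber order), `<folder>_MFI.csv` when MFI was computed, and
`<folder>_fibers.txt` (tab-separated; CNF rendered TRUE/FALSE, NA when no
nuclear channel was analyzed). Filenames are prefixed with the folder name
to avoid collisions across a batch. Intermediate label images are written
only under `--keep-intermediates`.

## Benchmark problem sizes

The test suite and the acceptance script use fields of 50 fibers
(~316×316 px at 1 μm/px) in batches of 10 per condition, which exercises
every code path at comfortable interactive runtimes while keeping ≥500
fibers per statistic.

## Known limitations

Merged fibers are not split by default (watershed is opt-in); tiled
acquisitions must be cropped by the user; edge fibers are measured by
visible area; MFI on endogenous stains inherits all staining variability
(validated here only against synthetic means); pixel size is trusted as
given — no TIFF-tag autodetection.
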