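# myofiber-morph

Automated morphometry of skeletal-muscle cross-sections from
immunofluorescence images. Given per-field folders of unmerged single-channel
TIFFs — a fiber-boundary stain such as Laminin or Dystrophin, a nuclear stain
such as DAPI, and optionally a protein-of-interest channel — the pipeline
segments individual myofibers, measures their cross-sectional area (CSA) in
μm², flags centrally nucleated fibers (CNF, the hallmark of recent
regeneration), and optionally reports each fiber's mean fluorescence
intensity (MFI). It is aimed at muscle-injury and regeneration studies
(e.g. mouse tibialis anterior at 7 days post-injury) where these counts are
otherwise collected by hand.

## Method

* **Segmentation.** The boundary channel is normalized, lightly smoothed and
  thresholded (Otsu, with a quantile fallback for degenerate histograms); the
  resulting boundary mask is morphologically closed to bridge small staining
  gaps, and the 4-connected components of its complement, holes filled,
  become candidate fibers. A `low`/`high` image-quality switch selects the
  gap-bridging strength. Because the basal-lamina stain is extracellular and
  shared between neighbours, each label is then grown halfway into the
  stained band, so CSA covers the fiber's true footprint.
* **Morphometry.** CSA = pixel count × (μm/pixel)². Candidates outside the
  user's size window (defaults 200–3000 μm², suited to regenerating muscle;
  use 200–4800 μm² for uninjured TA) are discarded; survivors are numbered
  1..N in raster order, matching the rendered overlay.
* **Central nucleation.** A fiber is a CNF when a detected nucleus centroid
  lies deeper into the fiber than `(1 − central_fraction) × √(area/π)` from
  its edge (default `central_fraction = 0.5`).
* **MFI.** Arithmetic mean of the raw intensity channel over the fiber's
  interior, no background subtraction, in native arbitrary units.
* **Validation toolkit.** Synthetic cross-sections (relaxed Voronoi
  tessellations with exact polygon ground truth, planted nuclei and known
  per-fiber intensity means) plus agreement statistics: percent accuracy
  `(1 − |manual − auto| / manual) × 100`, FP/FN rates from greedy IoU
  matching, least-squares regression and fixed-width histograms.

## Worked example

Generate two synthetic fields (30 fibers each, 40% with central nuclei,
known RFP means, mild noise) and quantify them:

```bash
myofiber-morph synth --out demo --n-scenes 2 --n-fibers 30 --seed 11 --noise-sigma 10
myofiber-morph run --input demo --um-per-pixel 1.0 --quality high \
    --min-size 200 --max-size 4800 --intensity-channel RFP
```

which prints

```
image                 fibers    mean CSA    %CNF
scene_001                 30      1997.2    40.0
scene_002                 30      1996.8    40.0
```

— all 30 planted fibers recovered per field, mean CSA within ~0.2% of the
generator's 2000 μm² target, and exactly the planted 40% CNF. Each scene
folder now holds a numbered overlay `final.tif`, and `demo/Results/`
contains `scene_001_CSA.csv` (comma-separated CSAs in fiber order),
`scene_001_MFI.csv` and `scene_001_fibers.txt`:

```
fiber	csa_um2	cnf	mfi_au
1	1999.0	TRUE	134.7111
2	1653.0	FALSE	62.4939
...
```

Fiber numbers cross-reference the overlay, so any fiber's CSA, nucleation
status and MFI can be looked up by eye.

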