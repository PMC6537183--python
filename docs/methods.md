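# Methods

## Problem and measurement model

A transverse muscle section stained for the sarcolemma (dystrophin +
α-II-spectrin, channel C1) and fast myosin heavy chain (MyHC, channel C2)
is acquired as a stitched 16-bit mosaic (camera dynamic range 0–4095,
calibration 0.647 µm/px by default). Each myofiber appears as a closed
bright membrane polygon on C1; type II fibers additionally show elevated
intracellular signal on C2. The analysis assumes: transverse (not oblique)
sectioning, membrane signal well above interior signal, and a single global
intensity regime per section (no strong local staining gradients beyond
what rolling-ball subtraction removes).

## Pipeline

**Enhancement.** (1) 3×3 median despeckle; border pixels use the in-bounds
neighborhood only. (2) Linear contrast stretch saturating 0.35 % of pixels
(half per tail) to the bit-depth extremes; constant images pass through
with a warning. (3) Rolling-ball background subtraction (radius 50 px
default). For radii > 8 px the standard shrink acceleration is used:
block-minimum downscale by `ceil(r/8)`, ball rolled at the reduced radius,
bilinear upsample of the background. The block minimum keeps the estimate
at or below the local signal floor, so few-pixel membrane ridges retain
their height (verified to 5 % in tests) while illumination gradients on
scales ≫ r are flattened.

**Segmentation.** The membrane is binarized with the
between-class-variance (Otsu) criterion evaluated on the exact integer
histogram — every representable gray level is a candidate threshold, and
the smallest maximizer is taken, which makes the result identical to
exhaustive search and independent of any binning choice. Gaps are sealed
by morphological closing with a disk of radius 4 px (~2.6 µm).
The radius was chosen from the geometry of sealing: a disk only seals a
through-gap when the membrane band is about as thick as the disk diameter,
and the apparent band in stained sections is 3–5 px; a radius of 2 px
cannot seal realistic few-micron staining discontinuities, while 4 px
seals them (including occasional double-width gaps from adjacent defects)
yet remains an order of magnitude below fiber scale (minor diameter
~40 µm), so distinct fibers are never bridged. Fibers are the 4-connected
components of the membrane complement; the membrane itself is effectively
8-connected, preventing diagonal leakage through 1-px lines. Components
reaching the image border (the exterior, and frame-clipped fibers) are
dropped; interior speckle holes are filled; labels are renumbered 1..n in
raster order, making ids reproducible.

**Exclusion.** Fibers with CSA < 200 or > 13,000 µm², circularity < 0.4,
or minor diameter < 1.5 µm are removed (strict comparisons: a fiber
exactly at a bound survives). The pectoral preset raises the bounds to
20,000 µm² and 8 µm for that muscle's larger fibers. Removed ids are
listed in the run log; survivors are renumbered consecutively.

**Tissue area.** Membrane ∪ fibers, closed with a 20 px disk (decomposed
footprint for whole-mosaic tractability) and hole-filled; area = pixel
count × (pixel size)². This is the "surface of analysis" used for count
normalization (fibers per 10 mm² = n / area_µm² × 10⁷).

**Typing.** One global threshold (same exact-histogram Otsu) over the C2
values of tissue pixels; each fiber's interior is eroded by 2 px to
exclude membrane bleed-through, and the fiber is type II when ≥ 50 % of
the eroded interior exceeds the threshold, type I otherwise. A fiber whose
eroded interior vanishes falls back to its full region (logged). The
pixel-fraction vote was preferred over mean intensity because it is robust
to partial staining and bright membrane contamination; the cutoff and
erosion are configurable. The classification is deliberately binary — no
IIa/IIx/hybrid subtyping.

**Morphometry.** CSA = pixel count × (pixel size)². Perimeter uses the
Crofton 4-direction estimator, which is near-unbiased for smooth convex
profiles (a rasterized disk of radius 30 px measures circularity 0.98;
chain-code estimators bias it below 0.91). Major/minor diameters are the
axes of the moment-equivalent ellipse — the particle-analysis convention —
not Feret calipers; an optional maximum-Feret column can be enabled for
comparison with manual caliper-style measurements. Circularity
`4πA/P²` is capped at 1.0 since discretization can push it slightly above.

**Scores.** Atrophy scores per fiber: CSA ≤ 500 µm² → 20, (500, 1000] →
10, (1000, 1500] → 5, (1500, 2000] → 1, > 2000 → 0. Hypertrophy: ≤ 4500 →
0, (4500, 5500] → 1, (5500, 6500] → 5, (6500, 7500] → 10, (7500, 8500] →
20, > 8500 → 30. The factor is the mean score over the fibers of a class
(all / I / II); printed integer bin edges are implemented as half-open
real intervals so every CSA has a defined score. Means are reported with
SEM; no inferential statistics are computed.

**Color maps.** Eight fixed bins per metric (CSA: ≤ 1000 … > 4000 µm²;
minor diameter: ≤ 10 … > 70 µm) with palette dark orchid `#9932CC`,
midnight blue `#191970`, cyan `#00B7EB`, dark cyan `#008B8B`, dark sea
green `#8FBC8F`, yellow `#FFFF00`, orange `#FFA500`, red `#FF0000`
(nearest standard named colors; overridable). Where printed bin edges
overlap at exactly 1000 µm², the lower bin wins. Maps carry a legend strip
and a 500 µm scale bar.

## Synthetic sections

The generator emulates the acquisition regime rather than microscopy
physics. Fiber target areas are lognormal (default mean 2400 µm², log-σ
0.4, floored at 250 µm² so interiors stay resolvable); the tissue disk is
sized to the summed target area; seeds are dart-thrown largest-first with
spacing 0.7·(rᵢ+rⱼ) (relaxed gradually if placement stalls) plus a
power-cell non-emptiness condition; fiber regions are the power (Laguerre)
diagram cells with weights rᵢ², rasterized via k-nearest-seed candidates.
The membrane is the ~4 px inter-cell boundary band at ~80 % of the camera
range (3300); interiors are dim on C1 (300) and either MyHC-positive
(3000) or negative (150) on C2 by a Bernoulli draw (default 52.6 % type
II). Gaussian read noise (σ 40 default) is added and the image clipped to
0–4095. Membrane dropout deletes contiguous arcs (disk stamps of radius
2 px on the band) until the requested pixel fraction is gone — deleted
membrane reverts to interior-level signal, as an unstained sarcolemma
stretch would. Everything derives from one seed; generation is bit-exact
reproducible.

What the generator does *not* model — point-spread blur, chromatic
offsets between channels, oblique fibers, necrotic/regenerating
morphology, internal nuclei, staining gradients across the section —
bounds what passing tests show: they validate the algorithmic chain
(enhancement, thresholding, topology repair, measurement, scoring), not
performance on adverse real-tissue optics.

## Problem sizes and numerical choices

Tests run mostly on 60–200-fiber sections (~0.6–1.3 Mpx); one end-to-end
check runs a whole-mosaic-scale section (~3000 fibers, 9300×9900 px),
which completes in a few minutes on one CPU. The acceptance script uses
300-fiber sections. Degenerate inputs are defined, not fatal: constant
images warn and pass through (contrast) or yield empty masks (threshold);
zero fibers produce header-only tables and "missing" score factors; a
zero-area section refuses count normalization. Label order, greedy
IoU-based truth matching (cutoff 0.5) and first-maximum threshold
tie-breaks are all deterministic.

## Known limitations

* Merged fibers are not split (no watershed); a fully unstained shared
  wall merges neighbors, and both are then lost to the size/shape filters
  or counted as one.
* The binarize/close/label chain is a classical reconstruction of
  membrane-based particle analysis; the original acquisition pipeline's
  exact operators are not public, so parameter defaults (radii, saturated
  fraction) are package choices, all exposed in configuration and echoed
  into run logs.
* Typing assumes a bimodal MyHC distribution within tissue; a section
  that is genuinely all-type-I (constant C2) is handled, but intermediate
  staining is forced into the binary call.
* Tissue area includes interstitial space after closing, so fibers per
  10 mm² is conservative relative to a fiber-only denominator.
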