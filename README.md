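# musclemorph

Automated histomorphometry of human skeletal-muscle cross-sections from
two-channel immunofluorescence mosaics.

Quantitative muscle histology — fiber sizes, counts, and the balance of
slow oxidative (type I) vs. fast glycolytic (type II) fibers — underpins
both research on aging/sarcopenia and the diagnosis of myopathies. Manual
measurement is slow, limited to small fields, and user-biased.
`musclemorph` analyzes entire digitized sections with no intervention:

1. **Enhance** the sarcolemma channel (C1, dystrophin/spectrin): 3×3 median
   despeckle → automatic contrast stretch → rolling-ball background
   subtraction.
2. **Segment** each myofiber: global between-class-variance threshold on the
   membrane, morphological gap closing, connected-component labeling of the
   enclosed interiors (border-touching profiles dropped).
3. **Filter** artifacts with user-adjustable exclusion bounds
   (defaults: CSA < 200 or > 13,000 µm², circularity < 0.4, minor
   diameter < 1.5 µm; a `pectoral` preset uses 20,000 µm² / 8 µm).
4. **Type** each fiber from the fast myosin heavy chain channel (C2):
   a section-wide threshold over tissue pixels, fiber called type II when
   ≥ 50 % of its eroded interior is MyHC-positive, type I by difference.
5. **Measure** per fiber: CSA (µm²), perimeter (µm), major/minor diameter
   (moment-ellipse axes, µm), circularity `4πA/P²`; and per section:
   tissue area, counts, fibers per 10 mm² (`n / area_µm² × 10⁷`), and
   atrophy/hypertrophy factors (fixed CSA score bins, summed and divided
   by the fiber count).
6. **Render** flattened segmentation overlays and 8-bin color-coded maps of
   CSA (≤ 1000 … > 4000 µm²) and minor diameter (≤ 10 … > 70 µm).

Because patient biopsies cannot be redistributed, the package includes a
first-class synthetic section generator (space-filling polygonal fibers
with lognormal CSA, bright membrane band, Bernoulli type-II assignment,
noise, exposure scaling and membrane-dropout arcs) with per-fiber ground
truth, so every stage is testable end to end.

## Worked example

```sh
python examples/01_simulate_and_analyze.py
```

prints

```
Generated section: 924x924 px, 120 fibers, tissue 0.27 mm^2

Detected 120 fibers (63 type I / 57 type II, 47.5% type II; truth 47.5%)
Mean CSA 1962 +/- 75 um^2, 4467 fibers per 10 mm^2
Atrophy factor 2.19, hypertrophy factor 0.02

Against ground truth: recall 100.0%, mean per-fiber IoU 0.995
```

All 120 generated fibers are recovered with near-exact boundaries
(IoU 0.995); the type split matches the ground truth exactly; the mean CSA
sits slightly below the generator's 2400 µm² target because the membrane
band is not part of a fiber's interior. The atrophy factor of 2.19 is in
the healthy range (inflammatory myopathies typically score ≳ 4).

Other examples: `02_batch_folder_analysis.py` (folder-driven batch with all
output files), `03_atrophy_scores_and_maps.py` (scores + color maps),
`04_robustness_checks.py` (exposure envelope and membrane dropout).

## Command line

```sh
musclemorph simulate --out data/ --n-fibers 200 --seed 1
musclemorph analyze data/ --out results/            # deltoid defaults
musclemorph analyze data/ --preset pectoral --min-area 250
```

`analyze` discovers `<sample>_C1.tif` / `<sample>_C2.tif` pairs
(8/16-bit single-channel TIFF), writes per-sample tables
(all / type I / type II), a run log echoing every parameter, a 16-bit label
TIFF, segmentation overlays and both color maps, plus a batch JSON report.
One failed sample never aborts the batch. Configuration comes from a TOML
file, a preset and/or flags (flags win); pixel size defaults to
0.647 µm/px.

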