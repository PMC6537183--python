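"""Folder-driven batch analysis, as a microscopy core would run it.

Writes three synthetic samples as <id>_C1.tif / <id>_C2.tif pairs into a
folder, then analyzes the whole folder in one call.  Every sample gets its
own subfolder with the three fiber tables (all / type I / type II), a
plain-text run log echoing the configuration, a 16-bit label TIFF, three
segmentation overlays and the two color-coded size maps.
"""

import tempfile
from pathlib import Path

import musclemorph as mm

folder = Path(tempfile.mkdtemp(prefix="musclemorph_demo_"))
mm.simulate_batch(folder, n_samples=3,
                  params=mm.SyntheticParams(n_fibers=80, seed=42))
print(f"Wrote 3 synthetic samples to {folder}")

config = mm.load_config()           # deltoid defaults: 200-13000 um^2,
                                    # circularity >= 0.4, minor >= 1.5 um
report = mm.run_batch(folder, config)

for entry in report["samples"]:
    print(f"  {entry['sample_id']}: {entry['status']}, "
          f"{entry['n_total']} fibers in {entry['seconds']:.1f} s")
print(f"Batch ok: {report['ok']}")

outputs = sorted(p.name for p in (folder / "synthetic_001").iterdir())
print("\nPer-sample outputs:")
for name in outputs:
    print("  ", name)
print("\nThe *_log.txt file records tissue area, counts and every "
      "configuration value used, so each number is auditable.")
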