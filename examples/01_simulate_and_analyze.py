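"""Generate a synthetic muscle section and run the full analysis on it.

Builds a 120-fiber two-channel section (C1 sarcolemma, C2 fast MyHC) with
known ground truth, runs preprocessing -> segmentation -> exclusion ->
typing -> morphometry, and prints the section summary next to the truth.
"""

import musclemorph as mm
from musclemorph.validation import match_fibers

params = mm.SyntheticParams(n_fibers=120, seed=7)
c1, c2, truth = mm.generate_section(params)
print(f"Generated section: {c1.shape[0]}x{c1.shape[1]} px, "
      f"{truth.n_fibers} fibers, tissue {truth.tissue_area_um2 / 1e6:.2f} mm^2")

result = mm.analyze_images(c1, c2, sample_id="demo")
s = result.summary

print(f"\nDetected {s.n_total} fibers "
      f"({s.n_type1} type I / {s.n_type2} type II, "
      f"{s.pct_type2:.1f}% type II; truth "
      f"{sum(t == 'II' for t in truth.types) / truth.n_fibers:.1%})")
mean_csa, sem_csa = s.means["all"]["csa_um2"]
print(f"Mean CSA {mean_csa:.0f} +/- {sem_csa:.0f} um^2, "
      f"{s.fibers_per_10mm2:.0f} fibers per 10 mm^2")
print(f"Atrophy factor {s.atrophy_factor_all:.2f}, "
      f"hypertrophy factor {s.hypertrophy_factor_all:.2f}")

m = match_fibers(truth.labels, result.labels)
print(f"\nAgainst ground truth: recall {m.recall:.1%}, "
      f"mean per-fiber IoU {m.mean_iou:.3f}")
print("A recall near 100% and IoU near 1 mean essentially every generated "
      "fiber was found with accurate boundaries.")
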