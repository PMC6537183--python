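"""Per-fiber measurements and section-level statistics.

Units are fixed throughout: areas in um^2, lengths in um, circularity
dimensionless.  "Minor/major diameter" are the axes of the ellipse with the
same normalized second central moments as the region (the measurement
convention of ImageJ-style particle analysis), *not* the minimum/maximum
Feret caliper widths; an optional maximum-Feret column is available for
comparison.  Perimeter uses the Crofton 4-direction estimator, which is
near-unbiased for smooth convex profiles such as fiber cross-sections.

Section-level scores:

* normalized fiber count  =  n / tissue_area_um2 * 1e7   (fibers per 10 mm^2)
* atrophy factor   = mean over fibers of an atrophy score of its CSA
  (<=500 um^2 -> 20, (500,1000] -> 10, (1000,1500] -> 5, (1500,2000] -> 1,
  >2000 -> 0)
* hypertrophy factor = mean of the hypertrophy score
  (<=4500 -> 0, (4500,5500] -> 1, (5500,6500] -> 5, (6500,7500] -> 10,
  (7500,8500] -> 20, >8500 -> 30)

The score-bin edges are printed as integer ranges in the histopathology
convention ("501 to 1000"); they are implemented as half-open real intervals
so that non-integer CSAs always receive a defined score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import regionprops

__all__ = [
    "FiberRecord", "SectionSummary", "ScoreBins",
    "ATROPHY_BINS", "HYPERTROPHY_BINS",
    "measure_fiber", "measure_fibers", "circularity",
    "normalized_fiber_count", "atrophy_factor", "hypertrophy_factor",
    "summarize_section",
]

SIZE_PARAMS = ("csa_um2", "perimeter_um", "major_diameter_um", "minor_diameter_um")


@dataclass
class FiberRecord:
    """Morphometry of one detected fiber, plus its type call."""

    fiber_id: int
    csa_um2: float
    perimeter_um: float
    major_diameter_um: float
    minor_diameter_um: float
    circularity: float
    fiber_type: str | None = None          # "I" or "II" once classified
    centroid_px: tuple[float, float] = (0.0, 0.0)   # (row, col)
    feret_max_um: float | None = None


@dataclass
class ScoreBins:
    """CSA score table: ``upper_bounds[i]`` closes score band i from above."""

    upper_bounds: tuple[float, ...]
    scores: tuple[float, ...]              # len == len(upper_bounds) + 1

    def score(self, csa_um2) -> np.ndarray:
        idx = np.digitize(np.asarray(csa_um2, dtype=float),
                          self.upper_bounds, right=True)
        return np.asarray(self.scores, dtype=float)[idx]


ATROPHY_BINS = ScoreBins((500.0, 1000.0, 1500.0, 2000.0), (20.0, 10.0, 5.0, 1.0, 0.0))
HYPERTROPHY_BINS = ScoreBins((4500.0, 5500.0, 6500.0, 7500.0, 8500.0),
                             (0.0, 1.0, 5.0, 10.0, 20.0, 30.0))


def circularity(csa_um2: float, perimeter_um: float) -> float:
    """4*pi*area/perimeter^2, capped at 1.0 (discretization can exceed it)."""
    if csa_um2 <= 0 or perimeter_um <= 0:
        raise ValueError("circularity needs positive area and perimeter")
    return min(1.0, 4.0 * np.pi * csa_um2 / perimeter_um**2)


def measure_fibers(
    labels: np.ndarray,
    pixel_size_um: float,
    include_feret: bool = False,
) -> list[FiberRecord]:
    """Measure every labeled region; records are ordered by label id."""
    records: list[FiberRecord] = []
    for prop in regionprops(labels):
        csa = float(prop.area) * pixel_size_um**2
        perim = float(prop.perimeter_crofton) * pixel_size_um
        major = float(prop.axis_major_length) * pixel_size_um
        minor = float(prop.axis_minor_length) * pixel_size_um
        circ = circularity(csa, perim) if perim > 0 else 1.0
        feret = float(prop.feret_diameter_max) * pixel_size_um if include_feret else None
        records.append(FiberRecord(
            fiber_id=int(prop.label),
            csa_um2=csa,
            perimeter_um=perim,
            major_diameter_um=major,
            minor_diameter_um=minor,
            circularity=circ,
            centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
            feret_max_um=feret,
        ))
    records.sort(key=lambda r: r.fiber_id)
    return records


def measure_fiber(region_mask: np.ndarray, pixel_size_um: float,
                  include_feret: bool = False) -> FiberRecord:
    """Measure a single region given as a boolean mask."""
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("region is empty")
    recs = measure_fibers(mask.astype(np.int32), pixel_size_um, include_feret)
    return recs[0]


def normalized_fiber_count(n_fibers: int, tissue_area_um2: float) -> float:
    """Fibers per 10 mm^2 of detected tissue: n / area * 1e7."""
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be positive")
    if n_fibers < 0:
        raise ValueError("fiber count must be non-negative")
    return n_fibers / tissue_area_um2 * 1e7


def atrophy_factor(csas_um2) -> float:
    """Mean atrophy score of the given fiber CSAs (higher = more atrophy)."""
    csas = np.asarray(csas_um2, dtype=float)
    if csas.size == 0:
        raise ValueError("atrophy factor is undefined for zero fibers")
    return float(ATROPHY_BINS.score(csas).mean())


def hypertrophy_factor(csas_um2) -> float:
    """Mean hypertrophy score of the given fiber CSAs."""
    csas = np.asarray(csas_um2, dtype=float)
    if csas.size == 0:
        raise ValueError("hypertrophy factor is undefined for zero fibers")
    return float(HYPERTROPHY_BINS.score(csas).mean())


@dataclass
class SectionSummary:
    """Section-level aggregate written to the per-sample run log."""

    tissue_area_um2: float
    n_total: int
    n_type1: int
    n_type2: int
    pct_type1: float | None
    pct_type2: float | None
    fibers_per_10mm2: float | None
    atrophy_factor_all: float | None
    atrophy_factor_1: float | None
    atrophy_factor_2: float | None
    hypertrophy_factor_all: float | None
    hypertrophy_factor_1: float | None
    hypertrophy_factor_2: float | None
    #: {"all"/"I"/"II": {param: (mean, sem)}} over the four size parameters
    means: dict = field(default_factory=dict)


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def summarize_section(records: list[FiberRecord], tissue_area_um2: float) -> SectionSummary:
    """Aggregate typed fiber records into the section summary.

    With zero fibers the counts are zero and all factors are missing (None).
    """
    n_total = len(records)
    groups = {
        "all": records,
        "I": [r for r in records if r.fiber_type == "I"],
        "II": [r for r in records if r.fiber_type == "II"],
    }
    if n_total and len(groups["I"]) + len(groups["II"]) != n_total:
        raise ValueError("every record must carry a type call (I or II)")

    means: dict = {}
    for name, grp in groups.items():
        means[name] = {}
        for param in SIZE_PARAMS:
            vals = np.array([getattr(r, param) for r in grp], dtype=float)
            means[name][param] = _mean_sem(vals) if vals.size else (None, None)

    def _factors(grp):
        if not grp:
            return None, None
        csas = [r.csa_um2 for r in grp]
        return atrophy_factor(csas), hypertrophy_factor(csas)

    at_all, hyp_all = _factors(groups["all"])
    at_1, hyp_1 = _factors(groups["I"])
    at_2, hyp_2 = _factors(groups["II"])

    return SectionSummary(
        tissue_area_um2=float(tissue_area_um2),
        n_total=n_total,
        n_type1=len(groups["I"]),
        n_type2=len(groups["II"]),
        pct_type1=100.0 * len(groups["I"]) / n_total if n_total else None,
        pct_type2=100.0 * len(groups["II"]) / n_total if n_total else None,
        fibers_per_10mm2=(normalized_fiber_count(n_total, tissue_area_um2)
                          if tissue_area_um2 > 0 else None),
        atrophy_factor_all=at_all,
        atrophy_factor_1=at_1,
        atrophy_factor_2=at_2,
        hypertrophy_factor_all=hyp_all,
        hypertrophy_factor_1=hyp_1,
        hypertrophy_factor_2=hyp_2,
        means=means,
    )
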