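"""End-to-end analysis: enhance -> segment -> filter -> type -> measure ->
summarize -> render, for one image pair or a whole folder.

The batch runner mirrors the original one-shot workflow: point it at a
folder of channel pairs, every sample is analyzed without intervention, all
outputs land in a per-sample subfolder, and a batch report records
per-sample status so one failed sample never aborts the run.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .config import AnalysisConfig
from .fibertype import classify_fibers, myhc_threshold
from .image import IntensityImage
from .io import (SamplePair, discover_sample_pairs, read_channel_image,
                 write_fiber_tables, write_run_log)
from .morphometry import SectionSummary, measure_fibers, summarize_section
from .preprocess import PreprocessConfig, preprocess_membrane
from .segment import (apply_exclusion_filters, binarize_membrane,
                      close_membrane_gaps, compute_tissue_area,
                      compute_tissue_mask, label_fibers)
from .visualize import (AREA_SPEC, MINOR_DIAMETER_SPEC, render_color_map,
                        render_segmentation_overlay, save_png)

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    """Everything computed for one sample."""

    sample_id: str
    records: list
    summary: SectionSummary
    labels: np.ndarray
    membrane_mask: np.ndarray
    tissue_mask: np.ndarray
    myhc_threshold: int
    removed_ids: list[int] = field(default_factory=list)

    @property
    def types(self) -> list[str]:
        return [r.fiber_type for r in self.records]


def analyze_images(c1: IntensityImage, c2: IntensityImage,
                   config: AnalysisConfig | None = None,
                   sample_id: str = "sample") -> SampleResult:
    """Run the full analysis on an in-memory image pair."""
    cfg = config or AnalysisConfig()
    if c1.shape != c2.shape:
        raise ValueError(f"{sample_id}: channel dimensions differ "
                         f"{c1.shape} vs {c2.shape}")
    pre_cfg = PreprocessConfig(
        despeckle_radius=cfg.despeckle.radius,
        saturated_fraction=cfg.contrast.saturated_fraction,
        ball_radius_px=cfg.background.ball_radius_px,
    )
    enhanced = preprocess_membrane(c1, pre_cfg)
    membrane = binarize_membrane(enhanced)
    membrane = close_membrane_gaps(membrane, cfg.segmentation.closing_radius_px)
    labels, n = label_fibers(membrane, exclude_border=cfg.segmentation.exclude_border)

    records = measure_fibers(labels, cfg.pixel_size_um,
                             include_feret=cfg.output.include_feret)
    labels, records, removed = apply_exclusion_filters(
        labels, records, cfg.exclusion.to_params())

    tissue = compute_tissue_mask(membrane, labels,
                                 cfg.segmentation.tissue_close_radius_px)
    tissue_area = compute_tissue_area(membrane, labels, cfg.pixel_size_um,
                                      tissue_mask=tissue)

    if tissue.any():
        threshold = myhc_threshold(c2, tissue)
        types = classify_fibers(labels, c2, threshold,
                                cfg.typing.positive_fraction_cutoff,
                                cfg.typing.erosion_px)
    else:
        threshold = 0
        types = []
    for rec, t in zip(records, types):
        rec.fiber_type = t

    summary = summarize_section(records, tissue_area)
    return SampleResult(sample_id=sample_id, records=records, summary=summary,
                        labels=labels, membrane_mask=membrane,
                        tissue_mask=tissue, myhc_threshold=int(threshold),
                        removed_ids=removed)


def analyze_sample(pair: SamplePair, config: AnalysisConfig,
                   out_root) -> SampleResult:
    """Analyze one discovered pair and write all per-sample outputs."""
    c1 = read_channel_image(pair.c1_path, config.pixel_size_um)
    c2 = read_channel_image(pair.c2_path, config.pixel_size_um)
    result = analyze_images(c1, c2, config, sample_id=pair.sample_id)
    write_outputs(result, config, out_root)
    return result


def write_outputs(result: SampleResult, config: AnalysisConfig, out_root) -> Path:
    """Write tables, run log, label TIFF, overlays and color maps."""
    sample_dir = Path(out_root) / result.sample_id
    sample_dir.mkdir(parents=True, exist_ok=True)
    sid = result.sample_id

    write_fiber_tables(result.records, sample_dir, sid,
                       config.output.table_format)
    write_run_log(result.summary, config.echo_lines(),
                  sample_dir / f"{sid}_log.txt", sid, __version__)

    if config.output.write_images:
        tifffile.imwrite(sample_dir / f"{sid}_labels.tif",
                         result.labels.astype(np.uint16), compression=None)
        types = result.types
        for mode in ("all", "typeI", "typeII"):
            rgb = render_segmentation_overlay(result.labels, types, mode)
            save_png(rgb, sample_dir / f"{sid}_seg_{mode}.png")
        for spec, tag in ((AREA_SPEC, "area"), (MINOR_DIAMETER_SPEC, "minor")):
            rgb = render_color_map(result.labels, result.records, spec,
                                   pixel_size_um=config.pixel_size_um)
            save_png(rgb, sample_dir / f"{sid}_map_{tag}.png")
    return sample_dir


def run_batch(folder, config: AnalysisConfig | None = None,
              out_root=None) -> dict:
    """Analyze every complete pair in ``folder``; never abort on one failure.

    Returns the batch report (also written as ``batch_report.json`` in the
    output root): per-sample status, fiber counts and timing, plus discovery
    warnings.  ``ok`` is False when any sample failed.
    """
    cfg = config or AnalysisConfig()
    folder = Path(folder)
    out_root = Path(out_root) if out_root is not None else folder
    pairs, warnings = discover_sample_pairs(
        folder, cfg.naming.c1_suffix, cfg.naming.c2_suffix)
    if not pairs:
        raise FileNotFoundError(
            f"no complete sample pairs in {folder}; expected files named "
            f"<sample>{cfg.naming.c1_suffix}.tif and "
            f"<sample>{cfg.naming.c2_suffix}.tif")
    report: dict = {"folder": str(folder), "version": __version__,
                    "warnings": warnings, "samples": []}
    for pair in pairs:
        t0 = time.perf_counter()
        entry = {"sample_id": pair.sample_id}
        try:
            result = analyze_sample(pair, cfg, out_root)
            entry.update(status="ok",
                         n_total=result.summary.n_total,
                         n_type1=result.summary.n_type1,
                         n_type2=result.summary.n_type2,
                         tissue_area_um2=result.summary.tissue_area_um2)
        except Exception as exc:
            logger.error("sample %s failed: %s", pair.sample_id, exc)
            entry.update(status="failed", error=str(exc),
                         traceback=traceback.format_exc())
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        report["samples"].append(entry)
    report["ok"] = all(s["status"] == "ok" for s in report["samples"])
    out_root.mkdir(parents=True, exist_ok=True)
    (out_root / "batch_report.json").write_text(json.dumps(report, indent=2))
    return report
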