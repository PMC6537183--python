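"""Image and table I/O plus folder-driven sample discovery.

The batch workflow is folder-driven: each sample contributes two
single-channel TIFFs named ``<sample><c1_suffix>.tif`` (sarcolemma) and
``<sample><c2_suffix>.tif`` (MyHC), discovered case-insensitively.  Pixel
calibration always comes from configuration, never from TIFF tags (the
physical calibration was established with a ruler, and tag metadata from
stitching software is unreliable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import DEFAULT_PIXEL_SIZE_UM, IntensityImage
from .morphometry import FiberRecord, SectionSummary

logger = logging.getLogger(__name__)

TIFF_EXTENSIONS = (".tif", ".tiff")

TABLE_COLUMNS = [
    "fiber_id", "csa_um2", "perimeter_um", "major_diameter_um",
    "minor_diameter_um", "circularity", "fiber_type",
    "centroid_row_px", "centroid_col_px",
]


@dataclass
class SamplePair:
    """One sample's pair of channel files (C1 membrane, C2 MyHC)."""

    sample_id: str
    c1_path: Path
    c2_path: Path


def discover_sample_pairs(
    folder,
    c1_suffix: str = "_C1",
    c2_suffix: str = "_C2",
) -> tuple[list[SamplePair], list[str]]:
    """Find complete C1/C2 pairs in a folder.

    Returns ``(pairs, warnings)`` with pairs sorted by sample id.  Unpaired
    channel files produce a warning entry (and a log record) instead of being
    silently dropped.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"no such folder: {folder}")
    c1_found: dict[str, Path] = {}
    c2_found: dict[str, Path] = {}
    for path in sorted(folder.iterdir()):
        if path.suffix.lower() not in TIFF_EXTENSIONS:
            continue
        stem = path.stem
        low = stem.lower()
        if low.endswith(c1_suffix.lower()):
            c1_found[stem[: len(stem) - len(c1_suffix)]] = path
        elif low.endswith(c2_suffix.lower()):
            c2_found[stem[: len(stem) - len(c2_suffix)]] = path
    pairs = []
    warnings = []
    for sid in sorted(set(c1_found) | set(c2_found)):
        if sid in c1_found and sid in c2_found:
            pairs.append(SamplePair(sid, c1_found[sid], c2_found[sid]))
        else:
            have = c1_suffix if sid in c1_found else c2_suffix
            miss = c2_suffix if sid in c1_found else c1_suffix
            msg = (f"sample '{sid}': found {have} but no matching {miss} "
                   f"file; sample skipped")
            warnings.append(msg)
            logger.warning(msg)
    return pairs, warnings


def read_channel_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> IntensityImage:
    """Read a single-channel 8/16-bit TIFF.

    RGB or multi-page files are rejected: the pipeline operates on the
    original single-channel planes, not on merged composites.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            n_pages = len(tf.pages)
            arr = tf.pages[0].asarray() if n_pages == 1 else None
    except Exception as exc:  # corrupt / not a TIFF
        raise ValueError(f"cannot read {path.name} as TIFF: {exc}") from exc
    if arr is None:
        raise ValueError(
            f"{path.name}: multi-page TIFF; expected one single-channel plane")
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel plane, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}; "
                         "expected 8- or 16-bit grayscale")
    return IntensityImage(arr, bit_depth=depth, pixel_size_um=pixel_size_um)


def write_channel_image(path, img: IntensityImage) -> None:
    """Write an uncompressed single-channel TIFF."""
    tifffile.imwrite(path, img.pixels, compression=None)


def records_to_frame(records: list[FiberRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "fiber_id": r.fiber_id,
            "csa_um2": r.csa_um2,
            "perimeter_um": r.perimeter_um,
            "major_diameter_um": r.major_diameter_um,
            "minor_diameter_um": r.minor_diameter_um,
            "circularity": r.circularity,
            "fiber_type": r.fiber_type,
            "centroid_row_px": r.centroid_px[0],
            "centroid_col_px": r.centroid_px[1],
        }
        if r.feret_max_um is not None:
            row["feret_max_um"] = r.feret_max_um
        rows.append(row)
    columns = TABLE_COLUMNS + (["feret_max_um"] if rows and "feret_max_um" in rows[0] else [])
    return pd.DataFrame(rows, columns=columns)


def write_fiber_tables(
    records: list[FiberRecord],
    out_dir,
    stem: str,
    table_format: str = "csv",
) -> dict[str, Path]:
    """Write the three per-fiber tables: all fibers, type I, type II.

    The row partition always satisfies |all| = |type I| + |type II|.
    """
    if table_format not in ("csv", "xlsx"):
        raise ValueError("table_format must be 'csv' or 'xlsx'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "all": records_to_frame(records),
        "typeI": records_to_frame([r for r in records if r.fiber_type == "I"]),
        "typeII": records_to_frame([r for r in records if r.fiber_type == "II"]),
    }
    paths = {}
    for kind, frame in frames.items():
        path = out_dir / f"{stem}_{kind}.{table_format}"
        if table_format == "csv":
            frame.to_csv(path, index=False)
        else:
            frame.to_excel(path, index=False)
        paths[kind] = path
    return paths


# --- run log ---------------------------------------------------------------

_LOG_FIELDS = [
    ("tissue_area_um2", "tissue area (um^2)"),
    ("n_total", "total fibers"),
    ("n_type1", "type I fibers"),
    ("n_type2", "type II fibers"),
    ("pct_type1", "type I (%)"),
    ("pct_type2", "type II (%)"),
    ("fibers_per_10mm2", "fibers per 10 mm^2"),
    ("atrophy_factor_all", "atrophy factor (all)"),
    ("atrophy_factor_1", "atrophy factor (type I)"),
    ("atrophy_factor_2", "atrophy factor (type II)"),
    ("hypertrophy_factor_all", "hypertrophy factor (all)"),
    ("hypertrophy_factor_1", "hypertrophy factor (type I)"),
    ("hypertrophy_factor_2", "hypertrophy factor (type II)"),
]


def write_run_log(summary: SectionSummary, config_lines: list[str], out_path,
                  sample_id: str, version: str) -> Path:
    """Plain-text per-sample log: summary values plus the config echo."""
    out_path = Path(out_path)
    lines = [f"musclemorph version: {version}", f"sample: {sample_id}", ""]
    for attr, label in _LOG_FIELDS:
        value = getattr(summary, attr)
        lines.append(f"{attr}: {'NA' if value is None else value!r}  # {label}")
    lines.append("")
    lines.append("[configuration]")
    lines.extend(config_lines)
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def parse_run_log(path) -> dict:
    """Parse a run log back into a dict (used for round-trip checks)."""
    out: dict = {}
    in_config = False
    for line in Path(path).read_text().splitlines():
        if line.strip() == "[configuration]":
            in_config = True
            out["config"] = []
            continue
        if in_config:
            if line.strip():
                out["config"].append(line)
            continue
        if ":" not in line:
            continue
        key, _, rest = line.partition(":")
        value = rest.split("#")[0].strip()
        if not value:
            continue
        key = key.strip()
        if key in ("musclemorph version", "sample"):
            out[key] = value
        elif value == "NA":
            out[key] = None
        else:
            try:
                out[key] = int(value)
            except ValueError:
                try:
                    out[key] = float(value)
                except ValueError:
                    out[key] = value
    return out
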