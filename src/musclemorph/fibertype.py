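"""Fiber-type calling from the fast myosin heavy chain (MyHC) channel.

Type II (fast, glycolytic) fibers stain for MyHC; type I (slow, oxidative)
fibers are the remainder, called by difference.  A single global threshold
is computed over the tissue pixels of the MyHC channel so that calls are
comparable across the whole section; each fiber is called positive when at
least ``positive_fraction_cutoff`` of its eroded interior exceeds the
threshold.  The 2-px erosion keeps membrane bleed-through out of the vote.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .segment import otsu_threshold

logger = logging.getLogger(__name__)


def myhc_threshold(c2_img, tissue_mask: np.ndarray) -> int:
    """Global MyHC positivity threshold over tissue pixels.

    Maximal between-class-variance criterion restricted to the tissue mask.
    If the channel is constant within tissue the constant itself is returned
    with a warning (no fiber will score positive: all type I).
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    px = c2_img.pixels
    if np.issubdtype(px.dtype, np.integer):
        vals = px[tissue_mask]
    else:
        vals = np.rint(px[tissue_mask]).astype(np.int64)
    if vals.min() == vals.max():
        logger.warning("myhc_threshold: constant channel within tissue; "
                       "all fibers will be type I")
        return int(vals[0])
    return otsu_threshold(vals)


def classify_fibers(
    labels: np.ndarray,
    c2_img,
    threshold: float,
    positive_fraction_cutoff: float = 0.5,
    erosion_px: int = 2,
) -> list[str]:
    """Call each labeled fiber "I" or "II".

    Returns the list of calls ordered by label id (1..n).  Fibers whose
    eroded interior vanishes fall back to the full region, with a log note.
    """
    if labels.shape != c2_img.pixels.shape:
        raise ValueError("labels and MyHC channel must share dimensions")
    n = int(labels.max())
    if n == 0:
        return []
    if not 0 < positive_fraction_cutoff <= 1:
        raise ValueError("positive_fraction_cutoff must be in (0, 1]")

    pos = c2_img.pixels > threshold
    if erosion_px > 0:
        # labeled regions are separated by >=1 px of membrane, so a global
        # erosion erodes each fiber independently
        eroded = ndimage.binary_erosion(labels > 0, structure=disk(erosion_px))
    else:
        eroded = labels > 0

    lab_flat = labels[eroded]
    total_er = np.bincount(lab_flat, minlength=n + 1)
    pos_er = np.bincount(lab_flat, weights=pos[eroded], minlength=n + 1)

    empty = np.flatnonzero(total_er[1:] == 0) + 1
    if empty.size:
        logger.info("classify_fibers: %d fibers with empty eroded interior, "
                    "using full region: %s", empty.size, empty.tolist())
        full_mask = np.isin(labels, empty)
        lab_full = labels[full_mask]
        total_full = np.bincount(lab_full, minlength=n + 1)
        pos_full = np.bincount(lab_full, weights=pos[full_mask], minlength=n + 1)
        total_er[empty] = total_full[empty]
        pos_er[empty] = pos_full[empty]

    frac = pos_er[1:] / np.maximum(total_er[1:], 1)
    return ["II" if f >= positive_fraction_cutoff else "I" for f in frac]
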