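"""Fiber segmentation from the enhanced sarcolemma channel.

The membrane network is binarized with a global between-class-variance
threshold, small staining gaps are sealed by morphological closing, and the
fibers are the connected components of the enclosed interior.  Exclusion
filters on size, circularity and minor diameter then remove debris, vessels
and cutting artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as morph_closing
from skimage.morphology import dilation, disk, erosion

logger = logging.getLogger(__name__)

#: 4-connectivity structuring element used for fiber interiors.
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ExclusionParams:
    """Bounds outside which a detected particle is not counted as a fiber.

    Defaults are the deltoid analysis settings; :meth:`pectoral` returns the
    larger-fiber preset used for pectoral biopsies.  All comparisons are
    strict: a fiber exactly at a bound survives.
    """

    min_area_um2: float = 200.0
    max_area_um2: float = 13_000.0
    min_circularity: float = 0.4
    min_minor_diameter_um: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.min_area_um2 < self.max_area_um2:
            raise ValueError("need 0 <= min_area < max_area")
        if not 0 <= self.min_circularity <= 1:
            raise ValueError("min_circularity must be in [0, 1]")
        if self.min_minor_diameter_um < 0:
            raise ValueError("min_minor_diameter_um must be >= 0")

    @classmethod
    def deltoid(cls) -> "ExclusionParams":
        return cls()

    @classmethod
    def pectoral(cls) -> "ExclusionParams":
        return cls(min_area_um2=200.0, max_area_um2=20_000.0,
                   min_circularity=0.4, min_minor_diameter_um=8.0)

    def excludes(self, csa_um2: float, circularity: float,
                 minor_diameter_um: float) -> bool:
        return (
            csa_um2 < self.min_area_um2
            or csa_um2 > self.max_area_um2
            or circularity < self.min_circularity
            or minor_diameter_um < self.min_minor_diameter_um
        )


def otsu_threshold(values: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold on an integer sample.

    Computed on the exact integer histogram (every representable gray level
    is a candidate), equivalent to exhaustive search over all thresholds t of
    the criterion  sigma_b^2(t) = w0 w1 (mu0 - mu1)^2  for the partition
    {<= t, > t}.  The smallest maximizing t is returned.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty sample")
    if not np.issubdtype(values.dtype, np.integer):
        raise TypeError("otsu_threshold expects integer values")
    vmin = int(values.min())
    hist = np.bincount(values.astype(np.int64) - vmin).astype(np.float64)
    if hist.size == 1:
        return vmin
    levels = np.arange(hist.size, dtype=np.float64)
    w0 = np.cumsum(hist)
    total = w0[-1]
    m0 = np.cumsum(hist * levels)
    mtot = m0[-1]
    w1 = total - w0
    # candidates t = vmin .. vmin+L-2 (both classes nonempty where w0,w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = sigma_b[:-1]
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return vmin + int(np.argmax(sigma_b))


def binarize_membrane(img) -> np.ndarray:
    """Threshold the preprocessed membrane channel into a boolean mask.

    Foreground (True) is membrane.  A constant image yields an empty mask
    with a warning.
    """
    px = img.pixels
    if px.min() == px.max():
        logger.warning("binarize_membrane: constant image, empty mask")
        return np.zeros(px.shape, dtype=bool)
    if np.issubdtype(px.dtype, np.integer):
        ints = px
    else:
        ints = np.rint(px).astype(np.int64)
    t = otsu_threshold(ints)
    return ints > t


def close_membrane_gaps(mask: np.ndarray, closing_radius_px: int = 4) -> np.ndarray:
    """Seal small breaks in the membrane network by disk closing.

    Closing is extensive (output is a superset of the input).  Gaps narrower
    than the disk are sealed provided the membrane is at least about as thick
    as the disk diameter; through-channels in very thin walls are a known
    limit of plain closing.
    """
    if closing_radius_px <= 0:
        return mask.copy()
    r = int(closing_radius_px)
    pad = r + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = morph_closing(padded, disk(r))
    return closed[pad:-pad, pad:-pad].astype(bool)


def label_fibers(mask: np.ndarray, exclude_border: bool = True) -> tuple[np.ndarray, int]:
    """Label fiber interiors from a closed membrane mask.

    Fibers are the 4-connected components of the complement of the membrane.
    The exterior background (any component reaching the image border) is
    discarded, which with ``exclude_border`` also drops fibers clipped by the
    frame.  Interior holes (unstained organelle-scale speckles) are filled,
    then labels are renumbered 1..n in raster-scan order of first pixel.
    """
    free = ~np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(free, structure=FOUR_CONN)
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32), 0
    border_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    if exclude_border:
        drop = border_labels
    else:
        drop = _exterior_labels(lab, border_labels)
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[drop] = False
    fibers = keep[lab]
    fibers = ndimage.binary_fill_holes(fibers)
    out, n_out = ndimage.label(fibers, structure=FOUR_CONN)
    return out.astype(np.int32), int(n_out)


def _exterior_labels(lab: np.ndarray, border_labels: np.ndarray) -> np.ndarray:
    """Heuristic exterior detection when border fibers are kept: a component
    touching two or more distinct image sides is treated as exterior."""
    sides = [lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]
    count = {}
    for side in sides:
        for v in np.unique(side):
            if v > 0:
                count[v] = count.get(v, 0) + 1
    return np.array([v for v, c in count.items() if c >= 2], dtype=lab.dtype)


def apply_exclusion_filters(labels: np.ndarray, records: list, params: ExclusionParams):
    """Drop fibers violating any exclusion bound; renumber survivors.

    ``records`` must hold one measured record per label, ordered by label id.
    Returns ``(new_labels, surviving_records, removed_ids)``; surviving labels
    are renumbered consecutively preserving order, and each surviving
    record's ``fiber_id`` is updated to match.
    """
    n = len(records)
    keep_ids = []
    removed_ids = []
    for rec in records:
        if params.excludes(rec.csa_um2, rec.circularity, rec.minor_diameter_um):
            removed_ids.append(rec.fiber_id)
        else:
            keep_ids.append(rec.fiber_id)
    lut = np.zeros(n + 1, dtype=np.int32)
    for new_id, old_id in enumerate(keep_ids, start=1):
        lut[old_id] = new_id
    new_labels = lut[labels]
    by_id = {rec.fiber_id: rec for rec in records}
    survivors = []
    for new_id, old_id in enumerate(keep_ids, start=1):
        rec = by_id[old_id]
        rec.fiber_id = new_id
        survivors.append(rec)
    if removed_ids:
        logger.info("exclusion filters removed %d fibers: %s",
                    len(removed_ids), removed_ids)
    return new_labels, survivors, removed_ids


def compute_tissue_mask(
    membrane_mask: np.ndarray,
    labels: np.ndarray,
    tissue_close_radius_px: int = 20,
) -> np.ndarray:
    """Mask of the whole tissue profile: membrane plus fibers, closed and
    hole-filled so interstitial space inside the section counts as tissue."""
    tissue = np.asarray(membrane_mask, bool) | (labels > 0)
    if not tissue.any():
        return tissue
    r = int(tissue_close_radius_px)
    if r > 0:
        pad = r + 1
        padded = np.pad(tissue, pad, mode="constant", constant_values=False)
        # decomposed disk keeps the closing tractable on whole-section mosaics
        seq = disk(r, decomposition="sequence")
        closed = erosion(dilation(padded, seq), seq)
        tissue = closed[pad:-pad, pad:-pad].astype(bool)
    return ndimage.binary_fill_holes(tissue)


def compute_tissue_area(
    membrane_mask: np.ndarray,
    labels: np.ndarray,
    pixel_size_um: float,
    tissue_close_radius_px: int = 20,
    tissue_mask: np.ndarray | None = None,
) -> float:
    """Total detected tissue surface in um^2 (the surface of analysis)."""
    if tissue_mask is None:
        tissue_mask = compute_tissue_mask(membrane_mask, labels, tissue_close_radius_px)
    return float(tissue_mask.sum()) * pixel_size_um**2
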