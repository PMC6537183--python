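"""Color-coded size maps and flattened segmentation overlays.

Two section-level pictures summarize fiber size at a glance: a map binned on
cross-sectional area (<=1000 to >4000 um^2) and one binned on minor diameter
(<=10 to >70 um), each with a fixed 8-color palette running dark orchid ->
blues -> greens -> yellow -> orange -> red from smallest to largest.  The
flattened overlays draw the outlines of all fibers, or of one type class,
over a black background for visual QC of the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from skimage.segmentation import find_boundaries

__all__ = [
    "ColorBin", "ColorMapSpec", "AREA_SPEC", "MINOR_DIAMETER_SPEC",
    "area_color_bin", "diameter_color_bin",
    "render_color_map", "render_segmentation_overlay", "save_png",
]


@dataclass(frozen=True)
class ColorBin:
    name: str
    rgb: tuple[int, int, int]


#: Palette shared by both metrics, smallest to largest.
PALETTE = (
    ColorBin("dark orchid", (0x99, 0x32, 0xCC)),
    ColorBin("night blue", (0x19, 0x19, 0x70)),
    ColorBin("cyan blue", (0x00, 0xB7, 0xEB)),
    ColorBin("dark cyan", (0x00, 0x8B, 0x8B)),
    ColorBin("dark sea green", (0x8F, 0xBC, 0x8F)),
    ColorBin("yellow", (0xFF, 0xFF, 0x00)),
    ColorBin("orange", (0xFF, 0xA5, 0x00)),
    ColorBin("red", (0xFF, 0x00, 0x00)),
)


@dataclass(frozen=True)
class ColorMapSpec:
    """Piecewise-constant mapping of a size metric onto the 8-bin palette.

    ``upper_bounds[i]`` closes bin i from above (inclusive); the last bin is
    open-ended.  Values at a shared printed edge (e.g. exactly 1000 um^2)
    fall in the lower bin.
    """

    metric: str                       # "area" | "minor_diameter"
    upper_bounds: tuple[float, ...]   # 7 finite edges for 8 bins
    bins: tuple[ColorBin, ...] = PALETTE

    def bin_index(self, value) -> np.ndarray:
        v = np.asarray(value, dtype=float)
        if np.any(v <= 0):
            raise ValueError(f"{self.metric} values must be positive")
        return np.digitize(v, self.upper_bounds, right=True)

    def color_of(self, value: float) -> ColorBin:
        return self.bins[int(self.bin_index(value))]


AREA_SPEC = ColorMapSpec(
    "area", (1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0, 4000.0))
MINOR_DIAMETER_SPEC = ColorMapSpec(
    "minor_diameter", (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0))


def area_color_bin(csa_um2: float) -> ColorBin:
    """Palette bin for a fiber CSA in um^2."""
    return AREA_SPEC.color_of(csa_um2)


def diameter_color_bin(minor_diameter_um: float) -> ColorBin:
    """Palette bin for a fiber minor diameter in um."""
    return MINOR_DIAMETER_SPEC.color_of(minor_diameter_um)


def render_color_map(
    labels: np.ndarray,
    records: list,
    spec: ColorMapSpec = AREA_SPEC,
    pixel_size_um: float | None = None,
    legend: bool = True,
    scale_bar_um: float = 500.0,
) -> np.ndarray:
    """Paint every fiber its size-bin color; background and membrane black.

    Returns an RGB uint8 array.  With ``legend=True`` a legend strip is
    appended below the map and, when ``pixel_size_um`` is given, a scale bar
    is drawn in the lower-right corner of the map.
    """
    n = int(labels.max())
    if len(records) != n:
        raise ValueError(f"{n} labels but {len(records)} records")
    lut = np.zeros((n + 1, 3), dtype=np.uint8)
    for rec in records:
        value = rec.csa_um2 if spec.metric == "area" else rec.minor_diameter_um
        lut[rec.fiber_id] = spec.color_of(value).rgb
    rgb = lut[labels]
    if legend:
        if pixel_size_um is not None:
            _draw_scale_bar(rgb, pixel_size_um, scale_bar_um)
        rgb = np.vstack([rgb, _legend_strip(spec, labels.shape[1])])
    return rgb


def _draw_scale_bar(rgb: np.ndarray, pixel_size_um: float, bar_um: float) -> None:
    h, w = rgb.shape[:2]
    bar_px = int(round(bar_um / pixel_size_um))
    if bar_px + 20 >= w:
        return
    thick = max(3, h // 200)
    r0 = h - 10 - thick
    c1 = w - 10
    rgb[r0:r0 + thick, c1 - bar_px:c1] = 255


def _legend_strip(spec: ColorMapSpec, width: int) -> np.ndarray:
    """One row of labeled color swatches rendered with PIL's bitmap font."""
    height = 36
    img = Image.new("RGB", (width, height), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    n = len(spec.bins)
    cell = max(1, width // n)
    edges = spec.upper_bounds
    for i, cb in enumerate(spec.bins):
        x0 = i * cell
        draw.rectangle([x0 + 2, 4, x0 + min(cell, 24), 18], fill=cb.rgb)
        if i == 0:
            label = f"<={edges[0]:g}"
        elif i == n - 1:
            label = f">{edges[-1]:g}"
        else:
            label = f"{edges[i - 1]:g}-{edges[i]:g}"
        if cell > 30:
            draw.text((x0 + 2, 20), label, fill=(200, 200, 200))
    return np.asarray(img, dtype=np.uint8)


_OVERLAY_COLORS = {"all": (255, 255, 255), "typeI": (0, 255, 0),
                   "typeII": (255, 64, 64)}


def render_segmentation_overlay(
    labels: np.ndarray,
    types: list[str],
    mode: str = "all",
) -> np.ndarray:
    """Outline the selected fiber class over a black background.

    ``types`` holds one call per label id (1..n).  Outline pixels are the
    inner 4-connected boundary of each selected region.
    """
    if mode not in _OVERLAY_COLORS:
        raise ValueError(f"mode must be one of {sorted(_OVERLAY_COLORS)}")
    n = int(labels.max())
    if len(types) != n:
        raise ValueError(f"{n} labels but {len(types)} type calls")
    if mode == "all":
        selected = np.ones(n + 1, dtype=bool)
    else:
        want = "I" if mode == "typeI" else "II"
        selected = np.zeros(n + 1, dtype=bool)
        for i, t in enumerate(types, start=1):
            selected[i] = t == want
    selected[0] = False
    boundaries = find_boundaries(labels, mode="inner", connectivity=1)
    boundaries &= selected[labels]
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    rgb[boundaries] = _OVERLAY_COLORS[mode]
    return rgb


def save_png(rgb: np.ndarray, path) -> None:
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
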