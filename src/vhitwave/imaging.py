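"""Rendering coherence maps as rasters, cropping, and per-patient tiling.

A coherence map is rendered as a heatmap with a fixed [0, 1] color scale
(viridis), linear time axis and log2 frequency axis, without axes or
annotations.  Three named crop styles select the time x frequency windows
used for classification; the three canal crops of one patient are tiled
into a single image in the fixed order horizontal, anterior, posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from matplotlib import colormaps
from scipy.ndimage import map_coordinates

from .coherence import CoherenceMap
from .traces import SCCS

#: per-tile raster resolution before tiling; keeps the three crops at equal
#: pixel weight prior to the final resize
TILE_RESOLUTION = 224

_VIRIDIS_LUT = np.ascontiguousarray(
    (np.asarray(colormaps["viridis"].colors) * 255.0).round().astype(np.uint8)
)


@dataclass(frozen=True)
class CropStyle:
    """A named time x frequency crop with its tiling direction."""

    name: str
    time_window: tuple[float, float]     # s
    freq_window: tuple[float, float]     # Hz
    tiling: str                          # "left-to-right" | "top-to-bottom"


CROP_STYLES: dict[str, CropStyle] = {
    "horizontal": CropStyle("horizontal", (0.10, 0.35), (4.0, 8.0), "left-to-right"),
    "vertical": CropStyle("vertical", (0.10, 0.20), (0.0, 12.0), "top-to-bottom"),
    "subtotal": CropStyle("subtotal", (0.10, 0.30), (0.0, 125.0), "left-to-right"),
}


@dataclass
class TiledImage:
    """Per-patient tiled crop image, ready for a feature-extraction backbone."""

    pixels: np.ndarray                   # H x W x 3, uint8
    style: CropStyle
    patient_id: str
    scc_order: tuple[str, ...] = SCCS

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels).save(path)


def value_to_rgb(values: np.ndarray) -> np.ndarray:
    """Fixed bijective color code on [0, 1] (256-level viridis)."""
    idx = np.clip(np.round(values * 255.0), 0, 255).astype(np.intp)
    return _VIRIDIS_LUT[idx]


def rgb_to_value(rgb: np.ndarray) -> np.ndarray:
    """Invert :func:`value_to_rgb` by nearest LUT entry (exact on rendered pixels)."""
    flat = rgb.reshape(-1, 3).astype(np.int32)
    d2 = ((flat[:, None, :] - _VIRIDIS_LUT[None, :, :].astype(np.int32)) ** 2).sum(-1)
    return (d2.argmin(axis=1) / 255.0).reshape(rgb.shape[:-1])


def render_coherence_raster(
    cmap: CoherenceMap,
    style: CropStyle,
    resolution: int = TILE_RESOLUTION,
) -> np.ndarray:
    """Rasterize one canal's MSWC crop to an RGB array.

    The frequency axis is log2-spaced from the window top down to the window
    bottom (clamped to the lowest grid frequency, since a log axis cannot
    reach 0 Hz); frequencies the scale grid cannot resolve are painted with
    the zero-coherence color, preserving the window geometry.  Bilinear
    sampling in (log2 f, t) space; deterministic byte-for-byte.
    """
    t0, t1 = style.time_window
    f_lo, f_hi = style.freq_window
    freqs = cmap.frequencies                       # decreasing with row
    f_grid_max, f_grid_min = freqs[0], freqs[-1]
    if t1 <= cmap.times[0] or t0 >= cmap.times[-1] or f_hi <= f_grid_min:
        raise ValueError(
            f"crop style {style.name!r} does not overlap the resolvable map"
        )
    f_lo = max(f_lo, f_grid_min)

    # pixel centers
    tpix = np.linspace(t0, t1, resolution)
    fpix = np.geomspace(f_hi, f_lo, resolution)    # top row = highest frequency

    # fractional row index in scale space: rows are uniform in log2(scale)
    voices = cmap.grid.voices_per_octave
    rows = voices * np.log2(f_grid_max / fpix)
    dt = float(cmap.times[1] - cmap.times[0])
    cols = (tpix - cmap.times[0]) / dt

    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    vals = map_coordinates(
        cmap.mswc, [rr, cc], order=1, mode="constant", cval=0.0
    )
    # out-of-grid frequencies -> zero-coherence color
    vals[(rr < 0) | (rr > len(freqs) - 1)] = 0.0
    return value_to_rgb(np.clip(vals, 0.0, 1.0))


def crop_and_tile(
    maps: dict[str, CoherenceMap],
    style: CropStyle,
    patient_id: str = "",
    output_size: int = 224,
    tile_resolution: int = TILE_RESOLUTION,
) -> TiledImage:
    """Crop all three canal maps and tile them into one patient image.

    Tiles are laid out left-to-right or top-to-bottom (per the style) in the
    fixed canal order horizontal, anterior, posterior, then the whole image
    is resized to ``output_size`` x ``output_size`` with bilinear
    interpolation.
    """
    missing = [scc for scc in SCCS if scc not in maps]
    if missing:
        raise ValueError(f"missing coherence map(s) for: {', '.join(missing)}")
    tiles = [
        render_coherence_raster(maps[scc], style, tile_resolution) for scc in SCCS
    ]
    axis = 1 if style.tiling == "left-to-right" else 0
    mosaic = np.concatenate(tiles, axis=axis)
    img = Image.fromarray(mosaic).resize(
        (output_size, output_size), resample=Image.BILINEAR
    )
    return TiledImage(
        pixels=np.asarray(img, dtype=np.uint8),
        style=style,
        patient_id=patient_id,
    )
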