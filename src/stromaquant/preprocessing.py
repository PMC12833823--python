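"""Slide preprocessing: tiling, tissue filtering, color normalization, labeling.

The slide is cut into non-overlapping square tiles (residual right/bottom
margins dropped). Tiles with too little structure — edge-pixel fraction
below 2% after grayscale Canny detection — are discarded as non-tissue.
Kept tiles are color-standardized by Reinhard normalization: match the
per-channel mean and standard deviation of the tile to a reference in the
decorrelated log color space lαβ. Ground-truth patch labels follow the 90%
rule: a patch is "tumor" only when tumor covers more than 90% of its area,
"mixed tumor-stroma" when tumor is present below that bound and coexists
with stroma, and otherwise takes its majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import feature

from .synthetic import CLASS_NAMES

# BT.601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

# Reinhard et al. RGB <-> LMS <-> lab transforms
_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOGLMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]]
)
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)
_EPS = 1e-6


@dataclass
class TileGrid:
    """Non-overlapping tile partition of a slide.

    Tiles use 0-based, half-open pixel windows
    [y0, y0 + tile_size) x [x0, x0 + tile_size), row-major order.
    """

    tile_size: int
    n_rows: int
    n_cols: int
    tiles: np.ndarray  # (n_tiles, 4) int: row, col, y0, x0
    edge_fraction: np.ndarray | None = None  # per tile, in [0, 1]
    keep_flags: np.ndarray | None = None  # bool per tile

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def windows(self, image: np.ndarray):
        for row, col, y0, x0 in self.tiles:
            yield (row, col), image[y0 : y0 + self.tile_size, x0 : x0 + self.tile_size]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.tiles, columns=["row", "col", "y0", "x0"])
        if self.edge_fraction is not None:
            df["edge_fraction"] = self.edge_fraction
        if self.keep_flags is not None:
            df["kept"] = self.keep_flags
        return df


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and sd in lαβ space (6 scalars)."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be >= 0")


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """8-bit RGB -> Reinhard lαβ (log-LMS opponent axes)."""
    flat = np.asarray(rgb, dtype=float).reshape(-1, 3) / 255.0
    lms = flat @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, _EPS))
    return (log_lms @ _LOGLMS2LAB.T).reshape(np.shape(rgb))


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    flat = np.asarray(lab, dtype=float).reshape(-1, 3)
    lms = np.power(10.0, flat @ _LAB2LOGLMS.T)
    rgb = np.clip(lms @ _LMS2RGB.T, 0.0, 1.0) * 255.0
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8).reshape(np.shape(lab))


def tile_slide(image: np.ndarray, tile_size: int = 224) -> TileGrid:
    """Partition into floor(H/ts) * floor(W/ts) tiles; margins dropped."""
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than one {tile_size}px tile")
    n_rows, n_cols = h // tile_size, w // tile_size
    tiles = np.array(
        [
            (r, c, r * tile_size, c * tile_size)
            for r in range(n_rows)
            for c in range(n_cols)
        ],
        dtype=np.int64,
    )
    return TileGrid(tile_size=tile_size, n_rows=n_rows, n_cols=n_cols, tiles=tiles)


def edge_density(tile: np.ndarray, canny_low: float = 10.0, canny_high: float = 25.0, sigma: float = 1.0) -> float:
    """Fraction of Canny edge pixels after BT.601 grayscale conversion."""
    tile = np.asarray(tile, dtype=float)
    if not np.all(np.isfinite(tile)):
        raise ValueError("tile contains non-finite pixel values")
    gray = tile @ _LUMA
    edges = feature.canny(gray, sigma=sigma, low_threshold=canny_low, high_threshold=canny_high)
    return float(edges.mean())


def compute_edge_fractions(
    grid: TileGrid, image: np.ndarray, canny_low: float = 10.0, canny_high: float = 25.0
) -> TileGrid:
    fracs = np.array(
        [edge_density(win, canny_low, canny_high) for _, win in grid.windows(image)]
    )
    return replace(grid, edge_fraction=fracs)


def filter_tiles(grid: TileGrid, threshold: float = 0.02) -> TileGrid:
    """Keep tiles whose edge fraction is at least ``threshold``.

    Patches with *less than* 2% edge pixels are discarded; ties at the
    threshold are kept.
    """
    if grid.edge_fraction is None:
        raise ValueError("edge fractions not computed; call compute_edge_fractions first")
    return replace(grid, keep_flags=grid.edge_fraction >= threshold)


def fit_reference(reference_tiles: list[np.ndarray]) -> NormalizationStats:
    """Channel-wise mean/sd of the pooled pixels of the reference tiles, in lαβ."""
    if not reference_tiles:
        raise ValueError("need at least one reference tile")
    pooled = np.concatenate([rgb_to_lab(t).reshape(-1, 3) for t in reference_tiles])
    return NormalizationStats(mean=pooled.mean(axis=0), sd=pooled.std(axis=0))


def normalize_tile(tile: np.ndarray, ref: NormalizationStats) -> np.ndarray:
    """Reinhard transfer: match tile lαβ statistics to the reference."""
    lab = rgb_to_lab(tile)
    flat = lab.reshape(-1, 3)
    mu, sd = flat.mean(axis=0), flat.std(axis=0)
    out = np.empty_like(flat)
    for ch in range(3):
        if sd[ch] < _EPS:  # degenerate channel maps to the reference mean
            out[:, ch] = ref.mean[ch]
        else:
            out[:, ch] = (flat[:, ch] - mu[ch]) * (ref.sd[ch] / sd[ch]) + ref.mean[ch]
    return lab_to_rgb(out.reshape(lab.shape))


def patch_label_from_mask(
    label_submap: np.ndarray,
    tumor_threshold: float = 0.90,
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> str:
    """Patch label from a ground-truth class submap (the 90% rule).

    "tumor" if tumor covers more than ``tumor_threshold`` of the patch;
    "mixed_tumor_stroma" if tumor is present at or below the threshold and
    stroma is also present; otherwise the majority pixel class, ties
    broken by class order.
    """
    sub = np.asarray(label_submap)
    if sub.size == 0:
        raise ValueError("empty label submap")
    counts = np.bincount(sub.ravel(), minlength=len(class_names))
    tumor_idx = class_names.index("tumor")
    stroma_idx = class_names.index("stroma")
    tumor_frac = counts[tumor_idx] / sub.size
    if tumor_frac > tumor_threshold:
        return "tumor"
    if tumor_frac > 0 and counts[stroma_idx] > 0:
        return "mixed_tumor_stroma"
    return class_names[int(np.argmax(counts))]
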