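"""Slide segmentation, tissue-class ratios, MTSR, and agreement analysis.

A slide is segmented by the tile pipeline (tile -> edge filter ->
normalize -> classify); each kept tile contributes one unit of area to its
predicted class. The tissue-class ratio is then

    ratio_c = (tiles of class c) / (all kept tissue tiles) * 100%

over the nine tissue classes, background excluded from the denominator;
the mixed tumor-stroma ratio (MTSR) is the entry for the
"mixed_tumor_stroma" class. Agreement between two measurement series
(e.g., model-derived vs. pathologist MTSR) is quantified by Pearson r,
the two-way random-effects single-measure intraclass correlation
ICC(2,1), and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize

from . import preprocessing as prep
from .classifier import TrainedClassifier, predict_patches
from .synthetic import CLASS_NAMES, SyntheticSlide

# Okabe-Ito colorblind-safe palette for the 9 tissue classes + gray background
OVERLAY_COLORS: dict[str, tuple[int, int, int]] = {
    "background": (200, 200, 200),
    "adipose": (230, 159, 0),
    "burn_deformation": (86, 180, 233),
    "inflammatory": (0, 158, 115),
    "mixed_tumor_stroma": (240, 228, 66),
    "muscle": (0, 114, 178),
    "necrosis": (213, 94, 0),
    "stroma": (204, 121, 167),
    "tumor": (0, 0, 0),
    "vessel": (255, 255, 255),
}


@dataclass
class ClassMap:
    """Per-tile predicted classes over a tile grid; discarded tiles excluded."""

    grid: prep.TileGrid
    tile_classes: np.ndarray  # int per tile; -1 for discarded tiles
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def kept_classes(self) -> np.ndarray:
        return self.tile_classes[self.tile_classes >= 0]


@dataclass(frozen=True)
class ClassRatioProfile:
    slide_id: str
    percentages: dict[str, float]  # 9 tissue classes, sum to 100
    mtsr: float
    kept_tile_count: int  # tissue tiles (denominator of the ratios)


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    slide_ids: tuple[str, ...]
    mtsr: float
    rule: str


@dataclass(frozen=True)
class AgreementReport:
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci: tuple[float, float]
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    loa: tuple[float, float]  # mean_diff +/- 1.96 sd
    n: int


def segment_slide(
    model: TrainedClassifier,
    image: np.ndarray,
    tile_size: int = 64,
    edge_threshold: float = 0.02,
    canny_low: float = 10.0,
    canny_high: float = 25.0,
    normalization: prep.NormalizationStats | None = None,
) -> ClassMap:
    """Tile, filter, optionally normalize, and classify a slide."""
    grid = prep.tile_slide(image, tile_size)
    grid = prep.compute_edge_fractions(grid, image, canny_low, canny_high)
    grid = prep.filter_tiles(grid, edge_threshold)
    kept_idx = np.flatnonzero(grid.keep_flags)
    if len(kept_idx) == 0:
        raise ValueError("no tissue detected: all tiles fell below the edge threshold")
    tiles = []
    windows = list(grid.windows(image))
    for i in kept_idx:
        _, win = windows[i]
        if normalization is not None:
            win = prep.normalize_tile(win, normalization)
        if tile_size != model.config.input_size:
            win = resize(
                win.astype(float), (model.config.input_size, model.config.input_size, 3),
                preserve_range=True, anti_aliasing=True,
            )
        tiles.append(win)
    pred, _ = predict_patches(model, np.stack(tiles))
    tile_classes = np.full(grid.n_tiles, -1, dtype=np.int64)
    tile_classes[kept_idx] = pred
    return ClassMap(grid=grid, tile_classes=tile_classes, class_names=model.class_names)


def oracle_class_map(slide: SyntheticSlide, tile_size: int = 64) -> ClassMap:
    """ClassMap from ground-truth labels (the 90% rule), bypassing the classifier.

    Tiles that are pure background are excluded, mirroring the edge filter.
    """
    grid = prep.tile_slide(slide.label_map, tile_size)
    classes = np.full(grid.n_tiles, -1, dtype=np.int64)
    for i, (_, sub) in enumerate(grid.windows(slide.label_map)):
        if np.all(sub == 0):
            continue
        label = prep.patch_label_from_mask(sub)
        classes[i] = CLASS_NAMES.index(label)
    return ClassMap(grid=grid, tile_classes=classes)


def compute_ratios(class_map: ClassMap, slide_id: str = "slide") -> ClassRatioProfile:
    """Tissue-class percentages from tile counts (exact rational arithmetic)."""
    kept = class_map.kept_classes
    tissue = kept[kept != 0]  # background-predicted tiles leave the denominator
    if len(tissue) == 0:
        raise ValueError("no tissue tiles: cannot compute class ratios")
    counts = np.bincount(tissue, minlength=len(class_map.class_names))
    total = int(counts[1:].sum())
    percentages = {
        name: float(Fraction(int(counts[i]), total) * 100)
        for i, name in enumerate(class_map.class_names)
        if i > 0
    }
    return ClassRatioProfile(
        slide_id=slide_id,
        percentages=percentages,
        mtsr=percentages["mixed_tumor_stroma"],
        kept_tile_count=total,
    )


def aggregate_patient(
    profiles: list[ClassRatioProfile],
    patient_id: str = "patient",
    rule: str = "tile-weighted mean",
) -> PatientProfile:
    """Patient-level MTSR across slides; default weights by kept-tile count."""
    if not profiles:
        raise ValueError("no slide profiles to aggregate")
    mtsrs = np.array([p.mtsr for p in profiles])
    if rule == "mean":
        value = mtsrs.mean()
    elif rule == "tile-weighted mean":
        w = np.array([p.kept_tile_count for p in profiles], dtype=float)
        value = float(np.average(mtsrs, weights=w))
    elif rule == "max":
        value = mtsrs.max()
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    return PatientProfile(
        patient_id=patient_id,
        slide_ids=tuple(p.slide_id for p in profiles),
        mtsr=float(value),
        rule=rule,
    )


def render_overlay(class_map: ClassMap) -> tuple[np.ndarray, dict[str, tuple[int, int, int]]]:
    """One colored pixel per tile (grid dimensions), plus the color legend."""
    grid = class_map.grid
    overlay = np.zeros((grid.n_rows, grid.n_cols, 3), dtype=np.uint8)
    legend: dict[str, tuple[int, int, int]] = {}
    for (row, col, _, _), cls in zip(grid.tiles, class_map.tile_classes):
        if cls < 0:
            color = OVERLAY_COLORS["background"]
            legend.setdefault("excluded", color)
        else:
            name = class_map.class_names[cls]
            color = OVERLAY_COLORS[name]
            legend.setdefault(name, color)
        overlay[row, col] = color
    return overlay, legend


# ------------------------------------------------------------- agreement

def icc_2_1(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Mean squares from the subject x rater two-way layout; the confidence
    interval uses the McGraw & Wong F-based bounds with Satterthwaite
    degrees of freedom.
    """
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    grand = x.mean()
    ms_r = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)  # rows: subjects
    ms_c = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)  # columns: raters
    sse = np.sum((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2)
    ms_e = sse / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 1.0, (1.0, 1.0)
    icc = (ms_r - ms_e) / denom

    # McGraw & Wong (1996) CI for ICC(A,1), Satterthwaite df
    if ms_e <= 0:
        return float(icc), (float(icc), float(icc))
    fj = ms_c / ms_e
    a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
    v = ((n - 1) * (k - 1) * a**2) / (
        (n - 1) * k**2 * icc**2 * fj**2 + (a - k * icc * fj) ** 2
    )
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (ms_r - f_u * ms_e) / (
        f_u * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
    )
    upper = n * (f_l * ms_r - ms_e) / (
        k * ms_c + (k * n - k - n) * ms_e + n * f_l * ms_r
    )
    return float(icc), (float(lower), float(upper))


def agreement(reference: np.ndarray, predicted: np.ndarray) -> AgreementReport:
    """Pearson r, ICC(2,1), and Bland-Altman statistics for paired series.

    The Bland-Altman difference is predicted - reference; limits of
    agreement are mean +/- 1.96 sd, and the CI of the mean difference uses
    the t distribution with n - 1 df.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be equal-length 1-D series")
    n = len(ref)
    if n < 3:
        raise ValueError("agreement analysis needs at least 3 pairs")
    if np.std(ref) == 0 or np.std(pred) == 0:
        r, p = np.nan, np.nan  # undefined for a constant series
    else:
        r, p = stats.pearsonr(ref, pred)
    icc, icc_ci = icc_2_1(ref, pred)
    diff = pred - ref
    md = diff.mean()
    sd = diff.std(ddof=1)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return AgreementReport(
        pearson_r=float(r),
        pearson_p=float(p),
        icc=icc,
        icc_ci=icc_ci,
        mean_diff=float(md),
        mean_diff_ci=(float(md - tcrit * se), float(md + tcrit * se)),
        loa=(float(md - 1.96 * sd), float(md + 1.96 * sd)),
        n=n,
    )


def profiles_to_frame(profiles: list[ClassRatioProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"slide_id": p.slide_id, **p.percentages, "mtsr": p.mtsr,
               "kept_tile_count": p.kept_tile_count}
        rows.append(row)
    return pd.DataFrame(rows)
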