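"""Synthetic H&E-like imagery with exact ground truth.

Real whole-slide images of bladder tumors are access-restricted and far too
large for a test suite, so this module fabricates the two image inputs the
pipeline needs:

* labeled texture *patches* — one of ten visually separable classes
  (background plus nine tissue types), used to train and benchmark the
  patch classifier;
* mosaic *slides* — a Voronoi tessellation of textured regions over a
  background frame, whose pixel-level class map (and hence every
  class-area fraction, including the mixed tumor-stroma ratio) is known
  exactly and serves as the oracle for ratio recovery.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

#: Fixed class order used everywhere: background first, then the nine
#: tissue classes in alphabetical order.
CLASS_NAMES: tuple[str, ...] = (
    "background",
    "adipose",
    "burn_deformation",
    "inflammatory",
    "mixed_tumor_stroma",
    "muscle",
    "necrosis",
    "stroma",
    "tumor",
    "vessel",
)

TISSUE_CLASSES: tuple[str, ...] = CLASS_NAMES[1:]
BACKGROUND = 0

# base RGB, pattern kind, pattern scale (px), evoking H&E morphology:
# near-white background, pink stroma/muscle, purple cell-dense classes.
_DEFAULT_TEXTURES: dict[str, tuple[tuple[int, int, int], str, int]] = {
    "background": ((245, 245, 245), "plain", 16),
    "adipose": ((238, 214, 166), "blobs", 14),
    "burn_deformation": ((120, 82, 142), "stripes", 9),
    "inflammatory": ((92, 62, 160), "speckle", 6),
    "mixed_tumor_stroma": ((192, 122, 172), "blobs", 10),
    "muscle": ((202, 84, 112), "stripes", 12),
    "necrosis": ((220, 182, 142), "speckle", 10),
    "stroma": ((232, 162, 192), "stripes", 16),
    "tumor": ((152, 92, 190), "blobs", 7),
    "vessel": ((198, 60, 62), "checker", 11),
}


@dataclass(frozen=True)
class TexturePalette:
    """Ten texture recipes plus a single ``difficulty`` knob.

    ``difficulty`` in [0, 1] pulls every base color toward the palette's
    grand mean and damps pattern contrast, so 0 gives trivially separable
    classes and 1 gives nearly indistinguishable ones.
    """

    difficulty: float = 0.0
    noise_sd: float = 8.0
    class_names: tuple[str, ...] = CLASS_NAMES
    textures: dict[str, tuple[tuple[int, int, int], str, int]] = field(
        default_factory=lambda: dict(_DEFAULT_TEXTURES)
    )

    def __post_init__(self) -> None:
        if len(self.class_names) != 10:
            raise ValueError("palette must define exactly 10 classes")
        if len(set(self.class_names)) != 10:
            raise ValueError("class names must be unique")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        missing = [c for c in self.class_names if c not in self.textures]
        if missing:
            raise ValueError(f"no texture recipe for classes: {missing}")

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; known: {list(self.class_names)}")

    def effective_color(self, name: str) -> np.ndarray:
        """Base color after difficulty interpolation toward the grand mean."""
        base = np.array([self.textures[c][0] for c in self.class_names], dtype=float)
        grand = base.mean(axis=0)
        color = np.asarray(self.textures[name][0], dtype=float)
        return (1.0 - self.difficulty) * color + self.difficulty * grand


@dataclass(frozen=True)
class SyntheticSlide:
    """RGB raster + pixel-level label map + exact tissue-area fractions."""

    image: np.ndarray  # (H, W, 3) uint8
    label_map: np.ndarray  # (H, W) int, indices into CLASS_NAMES
    true_ratios: dict[str, float]  # tissue class -> fraction of tissue pixels
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.label_map.shape:
            raise ValueError("image and label_map shapes differ")


def _pattern_field(kind: str, scale: int, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Deterministic texture field in roughly [-1, 1]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if kind == "plain":
        return np.zeros(shape)
    if kind == "stripes":
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / scale + phase)
    if kind == "checker":
        ox, oy = rng.integers(0, scale, size=2)
        return ((((xx + ox) // scale) + ((yy + oy) // scale)) % 2) * 2.0 - 1.0
    if kind == "blobs":
        n_blobs = max(1, int(h * w / (4.0 * scale**2)))
        cy = rng.uniform(0, h, n_blobs)
        cx = rng.uniform(0, w, n_blobs)
        r = rng.uniform(0.5 * scale, scale, n_blobs)
        fieldv = np.full(shape, -0.4)
        for y0, x0, ri in zip(cy, cx, r):
            mask = (yy - y0) ** 2 + (xx - x0) ** 2 <= ri**2
            fieldv[mask] = 1.0
        return fieldv
    if kind == "speckle":
        raw = rng.standard_normal(shape)
        sm = gaussian_filter(raw, sigma=max(scale / 4.0, 0.5))
        amax = np.abs(sm).max()
        return sm / amax if amax > 0 else sm
    raise ValueError(f"unknown pattern kind {kind!r}")


def _render_texture(
    palette: TexturePalette, class_name: str, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    color = palette.effective_color(class_name)
    _, kind, scale = palette.textures[class_name]
    contrast = 0.18 * (1.0 - 0.5 * palette.difficulty)
    fieldv = _pattern_field(kind, scale, shape, rng)
    img = color[None, None, :] * (1.0 + contrast * fieldv[:, :, None])
    img = img + rng.normal(0.0, palette.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def gen_texture_patch(
    palette: TexturePalette, class_id: str, size: int, seed: int
) -> np.ndarray:
    """One ``size`` x ``size`` RGB patch of the given class.

    Deterministic for a fixed seed; at difficulty 0 the mean color alone
    identifies the class.
    """
    if size < 32:
        raise ValueError("patch size must be >= 32")
    idx = palette.class_index(class_id)  # raises KeyError for unknown class
    rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
    return _render_texture(palette, class_id, (size, size), rng)


def gen_patch_dataset(
    palette: TexturePalette,
    n_per_class: int,
    size: int,
    seed: int,
    classes: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of patches and integer labels, ``n_per_class`` for each class."""
    classes = palette.class_names if classes is None else classes
    images, labels = [], []
    for name in classes:
        idx = palette.class_index(name)
        for j in range(n_per_class):
            # unique sub-seed per (dataset seed, class, replicate)
            sub = int(np.random.SeedSequence([seed, idx, j]).generate_state(1)[0] % (2**31))
            images.append(gen_texture_patch(palette, name, size, sub))
            labels.append(idx)
    return np.stack(images), np.asarray(labels)


def gen_slide(
    palette: TexturePalette,
    width: int,
    height: int,
    region_count: int,
    class_weights: np.ndarray,
    background_margin: int = 0,
    seed: int = 0,
) -> SyntheticSlide:
    """Voronoi-mosaic slide with exact per-class ground truth.

    ``region_count`` seed points are scattered over the tissue area (the
    frame of ``background_margin`` pixels stays background); each Voronoi
    cell is assigned one of the nine tissue classes drawn from
    ``class_weights``. ``true_ratios`` is re-tallied from the final label
    map, not from the weights.
    """
    weights = np.asarray(class_weights, dtype=float)
    if weights.shape != (9,):
        raise ValueError("class_weights must have length 9 (tissue classes)")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_weights must sum to 1, got {weights.sum()}")
    if region_count < 1:
        raise ValueError("region_count must be >= 1")
    m = background_margin
    if height - 2 * m <= 0 or width - 2 * m <= 0:
        raise ValueError("background_margin leaves no tissue area")

    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(m, height - m, region_count), rng.uniform(m, width - m, region_count)]
    )
    region_class = rng.choice(np.arange(1, 10), size=region_count, p=weights)

    yy, xx = np.mgrid[m : height - m, m : width - m]
    _, nearest = cKDTree(pts).query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    label_map = np.zeros((height, width), dtype=np.int64)
    label_map[m : height - m, m : width - m] = region_class[nearest].reshape(yy.shape)

    image = np.empty((height, width, 3), dtype=np.uint8)
    for idx in np.unique(label_map):
        name = palette.class_names[idx]
        tex_rng = np.random.default_rng(np.random.SeedSequence([seed, int(idx), 1]))
        tex = _render_texture(palette, name, (height, width), tex_rng)
        mask = label_map == idx
        image[mask] = tex[mask]

    true_ratios = true_ratios_from_label_map(label_map, palette.class_names)
    return SyntheticSlide(image=image, label_map=label_map, true_ratios=true_ratios, seed=seed)


def true_ratios_from_label_map(
    label_map: np.ndarray, class_names: tuple[str, ...] = CLASS_NAMES
) -> dict[str, float]:
    """Exact tissue-area fractions by pixel tally (background excluded)."""
    counts = np.bincount(label_map.ravel(), minlength=len(class_names))
    tissue_total = counts[1:].sum()
    if tissue_total == 0:
        raise ValueError("label map contains no tissue pixels")
    return {class_names[i]: counts[i] / tissue_total for i in range(1, len(class_names))}
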