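"""Grey-level co-occurrence texture: quantisation, GLCM, Haralick-style maps.

The texture description follows the classic co-occurrence recipe: the
colour image is converted to 8-bit luminance grey, rescaled to 5-bit (32
grey levels) to keep the co-occurrence matrix tractable, and a grey-level
co-occurrence matrix (GLCM) is accumulated in a sliding window around every
pixel.  Five statistics summarise each window's normalized matrix P:

    ASM           = sum P_ij^2
    Contrast      = sum P_ij (i-j)^2
    Dissimilarity = sum P_ij |i-j|
    Entropy       = -sum P_ij ln P_ij          (0 ln 0 := 0)
    Homogeneity   = sum P_ij / (1 + (i-j)^2)

The default offsets accumulate distance-1 pairs in the four directions
0/45/90/135 degrees symmetrically into one matrix - the common
rotation-robust convention.  Pixels whose window would cross the image
margin carry NaN in the texture maps and are excluded from object features.

The sliding-window implementation aggregates, for every grey-level pair
present in the image, exact integer window sums via summed-area tables, so
full texture maps cost O(pairs x pixels) independent of the kernel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_OFFSETS",
    "GLCMMatrix",
    "TextureVector",
    "rgb_to_grey",
    "quantize_grey",
    "compute_glcm",
    "texture_stats",
    "texture_maps",
    "object_feature_vector",
    "object_feature_table",
    "kernel_sweep_select",
    "TEXTURE_NAMES",
    "FEATURE_COLUMNS",
]

#: distance-1 pairs at 0, 45, 90 and 135 degrees (image row/col convention)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

TEXTURE_NAMES = ("asm", "contrast", "dissimilarity", "entropy", "homogeneity")

FEATURE_COLUMNS = tuple(
    f"{band}_{stat}" for band in ("R", "G", "B") for stat in ("mean", "sd")
) + tuple(
    f"{name}_{stat}" for name in TEXTURE_NAMES for stat in ("mean", "sd")
)


@dataclass
class GLCMMatrix:
    """Normalized co-occurrence matrix P over N grey levels."""

    P: np.ndarray
    n_levels: int
    symmetric: bool = True

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.n_levels, self.n_levels):
            raise ValueError("P must be (n_levels, n_levels)")
        if (P < 0).any():
            raise ValueError("P must be nonnegative")
        self.P = P


@dataclass(frozen=True)
class TextureVector:
    asm: float
    contrast: float
    dissimilarity: float
    entropy: float
    homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.contrast, self.dissimilarity,
                         self.entropy, self.homogeneity])


def rgb_to_grey(rgb: np.ndarray) -> np.ndarray:
    """Luminance grey (0.299 R + 0.587 G + 0.114 B) rounded to 8-bit."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[0] != 3:
        raise ValueError("expected (3, rows, cols) RGB array")
    grey = 0.299 * rgb[0] + 0.587 * rgb[1] + 0.114 * rgb[2]
    return np.clip(np.round(grey), 0, 255).astype(np.uint8)


def quantize_grey(image: np.ndarray, bits_out: int = 5) -> np.ndarray:
    """Rescale 8-bit grey values to ``bits_out`` bits: floor(v / 2**(8-b))."""
    if not 1 <= bits_out <= 8:
        raise ValueError("bits_out must be in 1..8")
    img = np.asarray(image)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("input values must lie in [0, 255]")
    return (img.astype(np.int64) // (2 ** (8 - bits_out))).astype(np.uint8)


def compute_glcm(window: np.ndarray, n_levels: int,
                 offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                 symmetric: bool = True) -> GLCMMatrix:
    """Co-occurrence matrix of one window of grey levels, normalized to sum 1."""
    w = np.asarray(window)
    if w.max(initial=0) >= n_levels:
        raise ValueError("window holds levels >= n_levels")
    counts = np.zeros((n_levels, n_levels), dtype=float)
    rows, cols = w.shape
    any_pairs = False
    for dr, dc in offsets:
        if abs(dr) >= rows or abs(dc) >= cols:
            continue
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        src = w[r0:r1, c0:c1]
        dst = w[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        np.add.at(counts, (src.ravel(), dst.ravel()), 1.0)
        any_pairs = True
    if not any_pairs:
        raise ValueError("window too small for every offset")
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return GLCMMatrix(counts / total, n_levels, symmetric)


def texture_stats(glcm: GLCMMatrix) -> TextureVector:
    """The five co-occurrence statistics of a normalized GLCM."""
    P = glcm.P
    total = P.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"GLCM is not normalized (sum={total})")
    i, j = np.indices(P.shape)
    d = i - j
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    return TextureVector(
        asm=float((P ** 2).sum()),
        contrast=float((P * d ** 2).sum()),
        dissimilarity=float((P * np.abs(d)).sum()),
        entropy=entropy,
        homogeneity=float((P / (1.0 + d ** 2)).sum()),
    )


def _window_sum(arr: np.ndarray, wh: int, ww: int) -> np.ndarray:
    """Exact sliding-window sums (top-left anchored) via summed-area table."""
    sat = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.int64)
    np.cumsum(arr, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    return (sat[wh:, ww:] - sat[:-wh, ww:] - sat[wh:, :-ww] + sat[:-wh, :-ww])


def texture_maps(levels: np.ndarray, kernel_size: int, n_levels: int = 32,
                 offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                 symmetric: bool = True) -> dict[str, np.ndarray]:
    """Per-pixel texture statistics over a centred sliding kernel window.

    Returns the five maps at image size with NaN in the margin of width
    ``(kernel_size - 1) // 2`` where the window would leave the image.
    """
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    if kernel_size < 3:
        raise ValueError("kernel_size must be >= 3")
    img = np.asarray(levels)
    rows, cols = img.shape
    if rows < kernel_size or cols < kernel_size:
        out = {name: np.full((rows, cols), np.nan) for name in TEXTURE_NAMES}
        return out
    if img.max(initial=0) >= n_levels:
        raise ValueError("levels must be < n_levels")
    k = kernel_size
    out_shape = (rows - k + 1, cols - k + 1)

    directed = list(offsets)
    if symmetric:
        directed += [(-dr, -dc) for dr, dc in offsets]

    counts_by_code: dict[int, np.ndarray] = {}
    total = np.zeros(out_shape, dtype=np.int64)
    for dr, dc in directed:
        if abs(dr) >= k or abs(dc) >= k:
            continue
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        code = (img[r0:r1, c0:c1].astype(np.int64) * n_levels
                + img[r0 + dr:r1 + dr, c0 + dc:c1 + dc])
        wh, ww = k - abs(dr), k - abs(dc)
        for value in np.unique(code):
            ws = _window_sum(code == value, wh, ww)
            prev = counts_by_code.get(int(value))
            counts_by_code[int(value)] = ws if prev is None else prev + ws
            total += ws

    totalf = total.astype(float)
    asm = np.zeros(out_shape)
    contrast = np.zeros(out_shape)
    dissim = np.zeros(out_shape)
    entropy = np.zeros(out_shape)
    homog = np.zeros(out_shape)
    for value, cnt in counts_by_code.items():
        i, j = divmod(value, n_levels)
        p = cnt / totalf
        asm += p * p
        d2 = (i - j) ** 2
        contrast += p * d2
        dissim += p * abs(i - j)
        homog += p / (1.0 + d2)
        nz = p > 0
        entropy[nz] -= p[nz] * np.log(p[nz])

    margin = (k - 1) // 2
    maps = {}
    for name, core in zip(TEXTURE_NAMES, (asm, contrast, dissim, entropy, homog)):
        full = np.full((rows, cols), np.nan)
        full[margin:rows - margin, margin:cols - margin] = core
        maps[name] = full
    return maps


def object_feature_vector(mask: np.ndarray, rgb: np.ndarray,
                          tex_maps: dict[str, np.ndarray]) -> np.ndarray:
    """16-value feature row: mean & population SD of 3 bands + 5 texture maps.

    Band statistics run over the object mask; texture statistics over masked
    pixels whose sliding window was valid (non-NaN).  An object entirely
    inside the texture margin raises.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("object mask is empty")
    feats = []
    for b in range(3):
        vals = np.asarray(rgb[b], dtype=float)[mask]
        feats += [vals.mean(), vals.std()]
    tex_valid = mask & ~np.isnan(tex_maps[TEXTURE_NAMES[0]])
    if tex_valid.sum() == 0:
        raise ValueError("object lies entirely inside the texture margin")
    for name in TEXTURE_NAMES:
        vals = tex_maps[name][tex_valid]
        feats += [vals.mean(), vals.std()]
    return np.asarray(feats)


def object_feature_table(objects, kernel_size: int, n_levels: int = 32,
                         bits: int = 5,
                         offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                         symmetric: bool = True) -> pd.DataFrame:
    """Feature table over extracted object images.

    ``objects`` is an iterable with ``id``, ``rgb`` (3, h, w), ``mask`` and
    ``label`` attributes (see ``pipeline.extract_object_images``).  Objects
    too small for the kernel are dropped with a warning.
    """
    rows = []
    index = []
    for obj in objects:
        grey = rgb_to_grey(obj.rgb)
        lv = quantize_grey(grey, bits)
        maps = texture_maps(lv, kernel_size, n_levels, offsets, symmetric)
        try:
            row = object_feature_vector(obj.mask, obj.rgb, maps)
        except ValueError:
            warnings.warn(
                f"object {obj.id} too small for kernel {kernel_size}; dropped")
            continue
        rows.append(np.concatenate([row, [obj.label]]))
        index.append(obj.id)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["label"],
                      index=pd.Index(index, name="object_id"))
    df["label"] = df["label"].astype(int)
    df.attrs["kernel_size"] = kernel_size
    return df


def kernel_sweep_select(objects, sizes=(3, 11, 19, 27, 35, 43, 51, 59),
                        seed: int = 0, gamma_grid=None, cost_grid=None,
                        ) -> tuple[int, pd.DataFrame]:
    """Sweep GLCM kernel sizes and pick the best by SVM validation accuracy.

    For each size the features are recomputed, the radial-basis SVM grid
    search is run over the 4-rotation fold plan, and the mean best
    validation accuracy is recorded.  Ties go to the smallest size.
    """
    from .classify import make_fold_plan, train_svm_grid

    sizes = sorted(sizes)
    records = []
    for size in sizes:
        feats = object_feature_table(objects, kernel_size=size)
        labels = feats["label"]
        if labels.nunique() < 2:
            raise ValueError("kernel sweep needs at least two classes")
        plan = make_fold_plan(list(feats.index), seed=seed)
        result = train_svm_grid(feats, plan, gamma_grid=gamma_grid,
                                cost_grid=cost_grid, seed=seed)
        records.append({
            "kernel_size": size,
            "n_objects": len(feats),
            "val_accuracy": float(np.mean(result.validation_accuracies)),
        })
    table = pd.DataFrame.from_records(records)
    best_idx = int(table["val_accuracy"].round(12).idxmax())
    return int(table.loc[best_idx, "kernel_size"]), table
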