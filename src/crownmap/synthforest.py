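"""Seeded synthetic forest scenes: orthomosaic + DSM + reference crowns.

Every stage of the pipeline is testable without a download by generating
scenes that emulate the structure of a mixed temperate forest seen from a
UAV at ~5 cm ground sampling distance: overlapping tree crowns of seven
classes (four tree types, two conifer species groups, plus non-forest),
each with a class-specific base colour and band-limited fine-scale foliage
texture, a cone-like surface-model bump per crown, and an understory /
bare-ground background.  Crown texture is band-limited Gaussian noise with
a class-specific spatial frequency: this is precisely the leaf-scale
contrast cue that separates similarly coloured classes, so classes are
separable by construction both for texture features and for the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

from .raster import GeoTransform, RasterGrid, SurfaceModel

__all__ = [
    "CLASS_NAMES",
    "ClassStyle",
    "DEFAULT_CLASS_STYLES",
    "ReferenceCrown",
    "SceneSpec",
    "Scene",
    "generate_scene",
    "rasterize_references",
]

#: The seven-class scheme, encoded 1..7.
CLASS_NAMES: dict[int, str] = {
    1: "deciduous broad-leaved tree",
    2: "deciduous coniferous tree",
    3: "evergreen broad-leaved tree",
    4: "Chamaecyparis obtusa",
    5: "Pinus elliottii / Pinus taeda",
    6: "Pinus strobus",
    7: "non-forest",
}


@dataclass(frozen=True)
class ClassStyle:
    """Visual recipe for one class: base colour, colour SD, texture frequency."""

    colour: tuple[float, float, float]  # 0..255 RGB mean
    colour_sd: float                    # grey-level SD of the foliage texture
    texture_freq: float                 # cycles per pixel of the band-limited noise


# Autumn-flavoured palette; frequencies spread over an octave ladder so the
# classes differ in leaf-scale contrast wavelength as well as hue.
DEFAULT_CLASS_STYLES: dict[int, ClassStyle] = {
    1: ClassStyle((186, 142, 62), 18.0, 0.060),
    2: ClassStyle((196, 108, 58), 20.0, 0.090),
    3: ClassStyle((58, 112, 66), 16.0, 0.125),
    4: ClassStyle((44, 84, 58), 18.0, 0.170),
    5: ClassStyle((88, 120, 70), 20.0, 0.225),
    6: ClassStyle((110, 140, 96), 18.0, 0.290),
    7: ClassStyle((168, 160, 150), 8.0, 0.020),
}


@dataclass
class ReferenceCrown:
    """A visually confirmed reference crown outline with its class label."""

    id: int
    polygon: Polygon
    class_label: int

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError("reference crown must have positive area")
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class label {self.class_label}")


@dataclass
class SceneSpec:
    """Study conditions of the default synthetic benchmark scene.

    512x512 pixels at 5 cm GSD (≈ 26 m x 26 m), 40 crowns over the 7-class
    scheme, crown radii 1.4-2.4 m, DSM at the coarser 10 cm GSD with one
    cone-shaped canopy bump per crown on a gently sloping ground plane.
    """

    shape: tuple[int, int] = (512, 512)
    cell_size: float = 0.05
    dsm_cell_size: float = 0.10
    n_crowns: int = 40
    classes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    class_styles: dict[int, ClassStyle] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_STYLES))
    radius_range: tuple[float, float] = (26.0, 42.0)   # pixels
    crown_height_range: tuple[float, float] = (8.0, 22.0)  # metres
    background_colour: tuple[float, float, float] = (92, 78, 58)
    background_sd: float = 10.0
    background_freq: float = 0.02
    rim_shadow_width: float = 3.0    # px, shadowed band just inside the outline
    rim_shadow_depth: float = 0.45   # brightness drop at the outline
    overlap_allowance: float = 0.15  # max centre-distance shortfall fraction
    max_place_tries: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crowns < len(self.classes):
            raise ValueError("need at least one crown per requested class")
        if self.radius_range[0] <= 0:
            raise ValueError("crown radii must be positive")
        for c in self.classes:
            if c not in CLASS_NAMES:
                raise ValueError(f"class {c} outside the 7-class scheme")


@dataclass
class Scene:
    """Generated scene bundle."""

    ortho: RasterGrid
    dsm: SurfaceModel
    references: list[ReferenceCrown]
    labels: dict[int, int]  # crown id -> class label
    spec: SceneSpec


def _bandlimited_noise(shape: tuple[int, int], freq: float, sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise band-passed around ``freq`` cycles/pixel."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fy, fx)
    halfwidth = max(freq * 0.5, 0.008)
    bandpass = np.exp(-0.5 * ((r - freq) / halfwidth) ** 2)
    shaped = np.fft.ifft2(np.fft.fft2(white) * bandpass).real
    s = shaped.std()
    if s > 0:
        shaped *= sd / s
    return shaped


def _crown_polygon(cx: float, cy: float, radius: float,
                   rng: np.random.Generator, n_vertices: int = 48) -> Polygon:
    """Jittered disk: a star-convex outline with low-order radial harmonics."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    wobble = np.zeros_like(theta)
    for order in (2, 3, 5):
        amp = rng.uniform(0.02, 0.07)
        phase = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.sin(order * theta + phase)
    r = radius * (1.0 + wobble)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return Polygon(zip(xs, ys))


def _place_centres(spec: SceneSpec, radii: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement honouring the overlap allowance."""
    rows, cols = spec.shape
    centres: list[tuple[float, float]] = []
    for k, rk in enumerate(radii):
        placed = False
        for _ in range(spec.max_place_tries):
            cx = rng.uniform(rk * 0.5, cols - rk * 0.5)
            cy = rng.uniform(rk * 0.5, rows - rk * 0.5)
            ok = True
            for (px, py), rp in zip(centres, radii[: len(centres)]):
                min_dist = (rk + rp) * (1.0 - spec.overlap_allowance)
                if np.hypot(cx - px, cy - py) < min_dist:
                    ok = False
                    break
            if ok:
                centres.append((cx, cy))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place crown {k} within the overlap allowance "
                f"after {spec.max_place_tries} tries")
    return np.asarray(centres)


def generate_scene(spec: SceneSpec | None = None) -> Scene:
    """Generate one deterministic synthetic forest scene from ``spec``."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape

    # class assignment: round-robin guarantees >= 1 crown per class, then shuffle
    class_seq = np.array([spec.classes[i % len(spec.classes)]
                          for i in range(spec.n_crowns)])
    rng.shuffle(class_seq)
    # place big crowns first: dart-throwing packs much better that way
    radii = np.sort(rng.uniform(*spec.radius_range, size=spec.n_crowns))[::-1]
    centres = _place_centres(spec, radii, rng)
    heights = rng.uniform(*spec.crown_height_range, size=spec.n_crowns)

    # background: understory/bare ground with its own coarse texture
    bg_noise = _bandlimited_noise((rows, cols), spec.background_freq,
                                  spec.background_sd, rng)
    ortho = np.empty((3, rows, cols))
    for b in range(3):
        ortho[b] = spec.background_colour[b] + bg_noise

    # one texture field per crown (trees are individuals): same frequency band
    # within a class, independent phase per crown
    crown_noise = [_bandlimited_noise((rows, cols),
                                      spec.class_styles[int(class_seq[k])].texture_freq,
                                      spec.class_styles[int(class_seq[k])].colour_sd,
                                      rng)
                   for k in range(spec.n_crowns)]

    # pixel (r, c) is the unit square [c, c+1] x [r, r+1], centre (c+.5, r+.5)
    yy, xx = np.mgrid[0:rows, 0:cols] + 0.5
    references: list[ReferenceCrown] = []
    labels: dict[int, int] = {}
    image_poly = box(0.0, 0.0, float(cols), float(rows))

    # DSM assembled at the coarser grid; ground is a gentle tilted plane
    drows = int(round(rows * spec.cell_size / spec.dsm_cell_size))
    dcols = int(round(cols * spec.cell_size / spec.dsm_cell_size))
    dyy, dxx = np.mgrid[0:drows, 0:dcols] + 0.5
    scale = spec.dsm_cell_size / spec.cell_size  # DSM px -> ortho px
    ground = 100.0 + 0.002 * dxx * spec.dsm_cell_size + 0.001 * dyy * spec.dsm_cell_size
    dsm = ground.copy()

    # full outlines first; the reference outline of each crown is its VISIBLE
    # extent (outline minus later-painted crowns), emulating visually
    # confirmed reference crowns in a layered canopy
    outlines = [_crown_polygon(*centres[k], radii[k], rng).intersection(image_poly)
                for k in range(spec.n_crowns)]
    occluder = None
    visible: list = [None] * spec.n_crowns
    for k in range(spec.n_crowns - 1, -1, -1):
        vis = outlines[k] if occluder is None else outlines[k].difference(occluder)
        if vis.is_empty or vis.area < 1.0:
            vis = outlines[k]  # fully hidden crowns keep their outline
        visible[k] = vis
        occluder = outlines[k] if occluder is None else occluder.union(outlines[k])

    for k in range(spec.n_crowns):
        crown_id = k + 1
        cls = int(class_seq[k])
        cx, cy = centres[k]
        poly = outlines[k]
        references.append(ReferenceCrown(crown_id, visible[k], cls))
        labels[crown_id] = cls

        # paint the ortho: later crowns overwrite earlier ones (canopy layering)
        dist = np.hypot(xx - cx, yy - cy)
        inside = _polygon_mask(poly, rows, cols)
        style = spec.class_styles[cls]
        # mild apex-to-rim shading plus a shadowed band along the outline,
        # emulating the dark inter-crown gaps a nadir view shows
        from scipy.ndimage import distance_transform_edt

        d_edge = distance_transform_edt(inside)
        rim = spec.rim_shadow_depth * np.clip(
            1.0 - d_edge / max(spec.rim_shadow_width, 1e-9), 0, 1)
        shading = (0.92 + 0.08 * np.clip(1.0 - dist / max(radii[k], 1e-9), 0, 1)
                   ) * (1.0 - rim)
        tex = crown_noise[k]
        for b in range(3):
            vals = style.colour[b] * shading + tex
            ortho[b][inside] = vals[inside]

        # cone-shaped canopy bump on the DSM (apex at the crown centre)
        ddist = np.hypot(dxx * scale - cx, dyy * scale - cy)
        cone = ground + heights[k] * np.clip(1.0 - ddist / radii[k], 0, 1)
        dsm = np.maximum(dsm, np.where(ddist <= radii[k], cone, ground))

    ortho = np.clip(np.round(ortho), 0, 255).astype(np.uint8)
    transform = GeoTransform(0.0, rows * spec.cell_size, spec.cell_size)
    dsm_transform = GeoTransform(0.0, rows * spec.cell_size, spec.dsm_cell_size)
    ortho_grid = RasterGrid(ortho, transform, band_names=("R", "G", "B"))
    surface = SurfaceModel(dsm, dsm_transform)
    return Scene(ortho_grid, surface, references, labels, spec)


def _polygon_mask(poly, rows: int, cols: int) -> np.ndarray:
    """Boolean pixel-centre containment mask for a polygon, bbox-limited."""
    from matplotlib.path import Path as MplPath

    mask = np.zeros((rows, cols), dtype=bool)
    if poly.is_empty:
        return mask
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, cols)
    r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, rows)
    if c1 <= c0 or r1 <= r0:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    geoms = getattr(poly, "geoms", [poly])
    sub = np.zeros(pts.shape[0], dtype=bool)
    for g in geoms:
        if g.is_empty or not isinstance(g, Polygon):
            continue
        path = MplPath(np.asarray(g.exterior.coords))
        hit = path.contains_points(pts)
        for hole in g.interiors:
            hit &= ~MplPath(np.asarray(hole.coords)).contains_points(pts)
        sub |= hit
    mask[r0:r1, c0:c1] = sub.reshape(r1 - r0, c1 - c0)
    return mask


def rasterize_references(references: list[ReferenceCrown],
                         shape: tuple[int, int]) -> np.ndarray:
    """Integer label raster of reference crowns; background 0.

    Later-placed crowns overwrite earlier ones where outlines overlap,
    mirroring canopy layering in the painted orthomosaic.
    """
    rows, cols = shape
    out = np.zeros((rows, cols), dtype=np.int32)
    for ref in references:
        mask = _polygon_mask(ref.polygon, rows, cols)
        out[mask] = ref.id
    return out
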