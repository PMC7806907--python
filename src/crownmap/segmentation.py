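"""Multiresolution region-merging segmentation of the layer stack.

Bottom-up object-based segmentation in the Baatz-Schaepe tradition: every
valid pixel starts as its own segment and adjacent segments merge while the
increase in weighted heterogeneity stays below ``scale**2``.  Heterogeneity
mixes a colour term (size-scaled increase of per-band population SD) with a
shape term (compactness and smoothness increases).  Merging proceeds in
synchronous local mutual-best-fitting passes: within a pass every segment
points at its cheapest admissible neighbour, and exactly the pairs that
point at each other are merged.  Ties are broken by seeded random edge
priorities, which makes runs bit-reproducible for a fixed seed.

The colour heterogeneity increase of merging segments ``a`` and ``b`` is

    dh_colour = sum_c w_c * (n_m*sd_c,m - (n_a*sd_c,a + n_b*sd_c,b))

with population SDs (defined for single-pixel segments), and the shape term

    dh_shape  = w_compact * dh_compactness + (1-w_compact) * dh_smoothness

with compactness = perimeter/sqrt(n), smoothness = perimeter/bbox-perimeter,
both size-scaled by n in the increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import box as shapely_box
from shapely import union_all
from shapely.geometry import Polygon

from .raster import RasterGrid

__all__ = [
    "SegmentationParams",
    "SegmentObject",
    "SegmentMap",
    "merge_cost",
    "multiresolution_segment",
    "polygonize_segments",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the region-merging criterion."""

    scale: float = 220.0
    shape_weight: float = 0.3
    compactness_weight: float = 0.8
    layer_weights: tuple[float, ...] | None = None  # None -> equal weights

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not 0 <= self.shape_weight < 1:
            raise ValueError("shape_weight must be in [0, 1)")
        if not 0 <= self.compactness_weight <= 1:
            raise ValueError("compactness_weight must be in [0, 1]")
        if self.layer_weights is not None:
            w = np.asarray(self.layer_weights, dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("layer weights must be nonnegative, one positive")


@dataclass
class SegmentObject:
    """Per-segment statistics maintained incrementally during merging."""

    id: int
    pixel_count: int
    means: np.ndarray        # per band
    sds: np.ndarray          # per band, population SD
    perimeter: int           # pixel-edge length incl. image border
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1) inclusive
    adjacency: dict[int, int] = field(default_factory=dict)  # neighbour -> shared edges

    @property
    def neighbours(self) -> set[int]:
        return set(self.adjacency)


@dataclass
class SegmentMap:
    """Label raster plus the per-segment object table."""

    labels: np.ndarray  # (rows, cols) int32, 0 = invalid/background
    objects: dict[int, SegmentObject]
    transform: object | None = None

    @property
    def n_segments(self) -> int:
        return len(self.objects)

    def recompute_object_stats(self, stack_values: np.ndarray) -> dict[int, SegmentObject]:
        """Batch recomputation of object statistics from the label grid.

        Independent of the incremental bookkeeping; used to assert the
        object-statistics consistency invariant.
        """
        out = {}
        for sid in self.objects:
            mask = self.labels == sid
            px = stack_values[:, mask].astype(float)
            r, c = np.nonzero(mask)
            out[sid] = SegmentObject(
                id=sid, pixel_count=int(mask.sum()),
                means=px.mean(axis=1), sds=px.std(axis=1),
                perimeter=_mask_perimeter(mask),
                bbox=(int(r.min()), int(r.max()), int(c.min()), int(c.max())),
                adjacency=dict(self.objects[sid].adjacency),
            )
        return out


def _mask_perimeter(mask: np.ndarray) -> int:
    """Pixel-edge perimeter of a boolean mask (image border counts)."""
    p = np.pad(mask, 1)
    return int((p[1:, :] != p[:-1, :]).sum() + (p[:, 1:] != p[:, :-1]).sum())


# ---------------------------------------------------------------------------
# merge cost
# ---------------------------------------------------------------------------

def merge_cost(a: SegmentObject, b: SegmentObject,
               params: SegmentationParams) -> float:
    """Heterogeneity increase of fusing two adjacent segments.

    Used only through comparison against ``scale**2``; the shape term can in
    pathological geometries be negative, which is fine for that use.
    """
    if b.id not in a.adjacency:
        raise ValueError(f"segments {a.id} and {b.id} are not adjacent")
    nb_bands = len(a.means)
    w = params.layer_weights
    weights = np.ones(nb_bands) if w is None else np.asarray(w, dtype=float)
    if len(weights) != nb_bands:
        raise ValueError("layer_weights length must match band count")

    na, nb = a.pixel_count, b.pixel_count
    nm = na + nb
    sum_a = a.means * na
    sum_b = b.means * nb
    sumsq_a = (a.sds ** 2 + a.means ** 2) * na
    sumsq_b = (b.sds ** 2 + b.means ** 2) * nb
    # n*sd == sqrt(n*sumsq - sum^2)
    h_a = (weights * np.sqrt(np.maximum(na * sumsq_a - sum_a ** 2, 0))).sum()
    h_b = (weights * np.sqrt(np.maximum(nb * sumsq_b - sum_b ** 2, 0))).sum()
    sum_m = sum_a + sum_b
    sumsq_m = sumsq_a + sumsq_b
    h_m = (weights * np.sqrt(np.maximum(nm * sumsq_m - sum_m ** 2, 0))).sum()
    dh_colour = h_m - (h_a + h_b)

    if params.shape_weight == 0:
        return float(dh_colour)

    shared = a.adjacency[b.id]
    pm = a.perimeter + b.perimeter - 2 * shared
    r0 = min(a.bbox[0], b.bbox[0]); r1 = max(a.bbox[1], b.bbox[1])
    c0 = min(a.bbox[2], b.bbox[2]); c1 = max(a.bbox[3], b.bbox[3])

    def cmpact(n, p):
        return n * p / np.sqrt(n)

    def smooth(n, p, bb):
        bperim = 2 * ((bb[1] - bb[0] + 1) + (bb[3] - bb[2] + 1))
        return n * p / bperim

    d_cmp = cmpact(nm, pm) - (cmpact(na, a.perimeter) + cmpact(nb, b.perimeter))
    d_smooth = smooth(nm, pm, (r0, r1, c0, c1)) - (
        smooth(na, a.perimeter, a.bbox) + smooth(nb, b.perimeter, b.bbox))
    dh_shape = params.compactness_weight * d_cmp + \
        (1 - params.compactness_weight) * d_smooth
    return float((1 - params.shape_weight) * dh_colour +
                 params.shape_weight * dh_shape)


# ---------------------------------------------------------------------------
# region-merging engine (flat-array implementation of the same criterion)
# ---------------------------------------------------------------------------

class _Engine:
    def __init__(self, values: np.ndarray, valid: np.ndarray,
                 params: SegmentationParams, seed: int):
        bands, rows, cols = values.shape
        self.params = params
        self.rng = np.random.default_rng(seed)
        w = params.layer_weights
        self.weights = (np.ones(bands) if w is None
                        else np.asarray(w, dtype=float))
        if len(self.weights) != bands:
            raise ValueError("layer_weights length must match band count")

        idx = np.full((rows, cols), -1, dtype=np.int64)
        ids = np.nonzero(valid.ravel())[0]
        n_seg = ids.size
        if n_seg == 0:
            raise ValueError("no valid pixels to segment")
        idx.ravel()[ids] = np.arange(n_seg)
        self.pixel_index = idx
        px = values.reshape(bands, -1)[:, ids].astype(float)

        self.n = np.ones(n_seg, dtype=np.int64)
        self.sum = px.copy()                      # (bands, n_seg)
        self.sumsq = px ** 2
        self.perim = np.full(n_seg, 4, dtype=np.int64)
        rr, cc = np.divmod(ids, cols)
        self.r0 = rr.copy(); self.r1 = rr.copy()
        self.c0 = cc.copy(); self.c1 = cc.copy()
        self.alive = np.ones(n_seg, dtype=bool)
        self.parent = np.arange(n_seg, dtype=np.int64)

        # initial 4-adjacency between valid pixels, one shared edge each
        adj: list[dict[int, int] | None] = [dict() for _ in range(n_seg)]
        for (sa, sb) in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
            pair_ok = (sa >= 0) & (sb >= 0)
            for u, v in zip(sa[pair_ok].ravel(), sb[pair_ok].ravel()):
                adj[u][v] = 1
                adj[v][u] = 1
        self.adj = adj

    # -- vectorised cost over an edge array --------------------------------
    def _edge_costs(self, ei: np.ndarray, ej: np.ndarray,
                    shared: np.ndarray) -> np.ndarray:
        p = self.params
        na = self.n[ei]; nb = self.n[ej]; nm = na + nb
        sa = self.sum[:, ei]; sb = self.sum[:, ej]
        qa = self.sumsq[:, ei]; qb = self.sumsq[:, ej]
        w = self.weights[:, None]
        h_a = (w * np.sqrt(np.maximum(na * qa - sa ** 2, 0))).sum(axis=0)
        h_b = (w * np.sqrt(np.maximum(nb * qb - sb ** 2, 0))).sum(axis=0)
        h_m = (w * np.sqrt(np.maximum(nm * (qa + qb) - (sa + sb) ** 2, 0))
               ).sum(axis=0)
        cost = (1 - p.shape_weight) * (h_m - h_a - h_b)
        if p.shape_weight > 0:
            pa = self.perim[ei]; pb = self.perim[ej]
            pm = pa + pb - 2 * shared
            r0 = np.minimum(self.r0[ei], self.r0[ej])
            r1 = np.maximum(self.r1[ei], self.r1[ej])
            c0 = np.minimum(self.c0[ei], self.c0[ej])
            c1 = np.maximum(self.c1[ei], self.c1[ej])
            d_cmp = nm * pm / np.sqrt(nm) - (na * pa / np.sqrt(na) +
                                             nb * pb / np.sqrt(nb))
            bb_m = 2.0 * ((r1 - r0 + 1) + (c1 - c0 + 1))
            bb_a = 2.0 * ((self.r1[ei] - self.r0[ei] + 1) +
                          (self.c1[ei] - self.c0[ei] + 1))
            bb_b = 2.0 * ((self.r1[ej] - self.r0[ej] + 1) +
                          (self.c1[ej] - self.c0[ej] + 1))
            d_sm = nm * pm / bb_m - (na * pa / bb_a + nb * pb / bb_b)
            cost = cost + p.shape_weight * (
                p.compactness_weight * d_cmp +
                (1 - p.compactness_weight) * d_sm)
        return cost

    def _collect_edges(self):
        ei, ej, sh = [], [], []
        for u in np.nonzero(self.alive)[0]:
            d = self.adj[u]
            for v, s in d.items():
                if v > u:
                    ei.append(u); ej.append(v); sh.append(s)
        return (np.asarray(ei, dtype=np.int64),
                np.asarray(ej, dtype=np.int64),
                np.asarray(sh, dtype=np.int64))

    def _merge(self, keep: int, kill: int) -> None:
        self.n[keep] += self.n[kill]
        self.sum[:, keep] += self.sum[:, kill]
        self.sumsq[:, keep] += self.sumsq[:, kill]
        shared = self.adj[keep].pop(kill)
        self.perim[keep] += self.perim[kill] - 2 * shared
        self.r0[keep] = min(self.r0[keep], self.r0[kill])
        self.r1[keep] = max(self.r1[keep], self.r1[kill])
        self.c0[keep] = min(self.c0[keep], self.c0[kill])
        self.c1[keep] = max(self.c1[keep], self.c1[kill])
        for v, s in self.adj[kill].items():
            if v == keep:
                continue
            self.adj[keep][v] = self.adj[keep].get(v, 0) + s
            dv = self.adj[v]
            dv.pop(kill, None)
            dv[keep] = self.adj[keep][v]
        self.adj[kill] = None
        self.alive[kill] = False
        self.parent[kill] = keep

    def run(self) -> None:
        threshold = self.params.scale ** 2
        while True:
            ei, ej, shared = self._collect_edges()
            if ei.size == 0:
                break
            cost = self._edge_costs(ei, ej, shared)
            ok = cost < threshold
            if not ok.any():
                break
            ei, ej, cost = ei[ok], ej[ok], cost[ok]
            prio = self.rng.random(ei.size)  # seeded tie-break
            order = np.lexsort((prio, cost))
            ei_s, ej_s = ei[order], ej[order]
            pos = np.arange(ei_s.size)
            first = np.full(self.parent.size, np.iinfo(np.int64).max)
            np.minimum.at(first, ei_s, pos)
            np.minimum.at(first, ej_s, pos)
            mutual = (first[ei_s] == pos) & (first[ej_s] == pos)
            if not mutual.any():
                break
            for u, v in zip(ei_s[mutual], ej_s[mutual]):
                self._merge(min(u, v), max(u, v))

    def result(self, transform) -> SegmentMap:
        # resolve union-find and relabel 1..K in row-major first-pixel order
        parent = self.parent
        root = parent.copy()
        while True:
            nxt = parent[root]
            if (nxt == root).all():
                break
            root = nxt
        labels = np.zeros(self.pixel_index.shape, dtype=np.int32)
        valid = self.pixel_index >= 0
        seg_of_pixel = root[self.pixel_index[valid]]
        uniq, inv = np.unique(seg_of_pixel, return_inverse=True)
        # np.unique sorts by internal id == row-major first pixel: stable order
        labels[valid] = inv.astype(np.int32) + 1
        new_id = {int(old): i + 1 for i, old in enumerate(uniq)}
        objects: dict[int, SegmentObject] = {}
        for old in uniq:
            old = int(old)
            sid = new_id[old]
            n = int(self.n[old])
            means = self.sum[:, old] / n
            var = np.maximum(self.sumsq[:, old] / n - means ** 2, 0.0)
            adjacency = {new_id[int(v)]: int(s)
                         for v, s in self.adj[old].items()}
            objects[sid] = SegmentObject(
                id=sid, pixel_count=n, means=means, sds=np.sqrt(var),
                perimeter=int(self.perim[old]),
                bbox=(int(self.r0[old]), int(self.r1[old]),
                      int(self.c0[old]), int(self.c1[old])),
                adjacency=adjacency)
        return SegmentMap(labels, objects, transform)


def multiresolution_segment(stack: RasterGrid, params: SegmentationParams,
                            seed: int = 0) -> SegmentMap:
    """Segment the layer stack into crown-scale objects by region merging.

    Starts from single-pixel segments; merges mutually best-fitting adjacent
    pairs whose cost stays below ``params.scale**2``; terminates when no
    admissible merge remains.  Deterministic for fixed input, params, seed.
    """
    values = np.asarray(stack.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty raster")
    if stack.layer_weights and params.layer_weights is None:
        params = SegmentationParams(params.scale, params.shape_weight,
                                    params.compactness_weight,
                                    tuple(stack.layer_weights))
    engine = _Engine(values, stack.valid_mask(), params, seed)
    engine.run()
    return engine.result(stack.transform)


def polygonize_segments(segmap: SegmentMap) -> list[tuple[int, Polygon]]:
    """One pixel-edge polygon per segment; polygon area equals pixel count.

    Coordinates are pixel units: pixel (r, c) is the square [c, c+1]x[r, r+1].
    """
    out = []
    labels = segmap.labels
    for sid, obj in segmap.objects.items():
        r0, r1, c0, c1 = obj.bbox
        sub = labels[r0:r1 + 1, c0:c1 + 1] == sid
        rr, cc = np.nonzero(sub)
        boxes = shapely_box(cc + c0, rr + r0, cc + c0 + 1, rr + r0 + 1)
        out.append((sid, union_all(boxes)))
    return out
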