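"""Scoring a segment map against reference crowns.

Each evaluated segment is placed in exactly one of five categories by its
overlap with the reference crowns, where overlap is the intersection area
divided by the reference-crown area (configurably intersection-over-union):

* Matched          - one crown captured, overlap > 80 %
* Nearly matched   - one crown, overlap 60-80 %
* Split            - one crown, overlap 20-60 %
* Merged           - two or more crowns each overlapped > 20 %; subdivided
                     into one-class and multi-class merges
* Fragmented       - covers crowns only marginally (every overlap <= 20 %)

Interval closure at exactly 60 % and exactly 20 % is downward (0.60 ->
Split, 0.20 does not count toward a merge).  Segments that intersect no
crown at all and whose centroid lies outside every crown are background and
are excluded from the tabulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .segmentation import SegmentMap, polygonize_segments
from .synthforest import ReferenceCrown

__all__ = [
    "MatchCategory",
    "MatchThresholds",
    "overlap_fraction",
    "categorize_segment",
    "tabulate_matches",
    "crown_recovery",
]


class MatchCategory(Enum):
    MATCHED = "Matched"
    NEARLY_MATCHED = "Nearly matched"
    SPLIT = "Split"
    MERGED_ONE_CLASS = "Merged one-class"
    MERGED_MULTI_CLASS = "Merged multi-class"
    FRAGMENTED = "Fragmented"


TABLE_COLUMNS = [c.value for c in MatchCategory]


@dataclass(frozen=True)
class MatchThresholds:
    """Overlap-fraction decision boundaries of the category scheme."""

    matched_min: float = 0.80
    nearly_min: float = 0.60
    split_min: float = 0.20
    use_iou: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.split_min < self.nearly_min < self.matched_min < 1:
            raise ValueError("thresholds must satisfy 0 < split < nearly < matched < 1")


def overlap_fraction(segment_polygon: BaseGeometry, reference: ReferenceCrown,
                     use_iou: bool = False) -> float:
    """Fraction of the reference crown captured by the segment.

    Default denominator is the reference-crown area (crown capture);
    ``use_iou`` switches to intersection-over-union.
    """
    ref_area = reference.polygon.area
    if ref_area <= 0:
        raise ValueError("reference crown has zero area")
    inter = segment_polygon.intersection(reference.polygon).area
    if use_iou:
        union = segment_polygon.union(reference.polygon).area
        return inter / union if union > 0 else 0.0
    return inter / ref_area


def categorize_segment(segment_polygon: BaseGeometry,
                       references: list[ReferenceCrown],
                       thresholds: MatchThresholds = MatchThresholds(),
                       ) -> MatchCategory:
    """Assign one of the five categories to a segment polygon."""
    if not references:
        raise ValueError("at least one reference crown is required")
    overlaps = [(overlap_fraction(segment_polygon, r, thresholds.use_iou), r)
                for r in references]
    covered = [(o, r) for o, r in overlaps if o > thresholds.split_min]
    if len(covered) == 0:
        return MatchCategory.FRAGMENTED
    if len(covered) >= 2:
        classes = {r.class_label for _, r in covered}
        return (MatchCategory.MERGED_ONE_CLASS if len(classes) == 1
                else MatchCategory.MERGED_MULTI_CLASS)
    o, _ = covered[0]
    if o > thresholds.matched_min:
        return MatchCategory.MATCHED
    if o > thresholds.nearly_min:
        return MatchCategory.NEARLY_MATCHED
    return MatchCategory.SPLIT


def _is_background(segment_polygon: BaseGeometry,
                   references: list[ReferenceCrown]) -> bool:
    """Non-forest segment: no intersection and centroid outside all crowns."""
    centroid = segment_polygon.centroid
    for r in references:
        if segment_polygon.intersection(r.polygon).area > 0:
            return False
        if r.polygon.contains(centroid):
            return False
    return True


def tabulate_matches(segmap: SegmentMap, references: list[ReferenceCrown],
                     thresholds: MatchThresholds = MatchThresholds(),
                     areas: dict[str, BaseGeometry] | None = None,
                     polygons: list[tuple[int, BaseGeometry]] | None = None,
                     ) -> pd.DataFrame:
    """Per-area category counts of evaluated segments.

    ``areas`` maps area names to polygons; segments are tallied in every
    named area containing their centroid (default: one area spanning all).
    Background segments (no crown contact) are excluded.
    """
    if polygons is None:
        polygons = polygonize_segments(segmap)
    tree = STRtree([r.polygon for r in references])
    rows: dict[str, dict[str, int]] = {}
    area_items = list((areas or {"all": None}).items())
    for name, _ in area_items:
        rows[name] = {c: 0 for c in TABLE_COLUMNS}
    seen = {name: 0 for name, _ in area_items}
    for sid, poly in polygons:
        nearby = [references[i] for i in tree.query(poly)]
        if not nearby or _is_background(poly, nearby):
            continue
        category = categorize_segment(poly, nearby, thresholds)
        centroid = poly.centroid
        for name, region in area_items:
            if region is None or region.contains(centroid):
                rows[name][category.value] += 1
                seen[name] += 1
    for name, total in seen.items():
        if total == 0:
            warnings.warn(f"area {name!r} contains no evaluated segments")
    return pd.DataFrame.from_dict(rows, orient="index")[TABLE_COLUMNS]


def crown_recovery(segmap: SegmentMap, references: list[ReferenceCrown],
                   thresholds: MatchThresholds = MatchThresholds(),
                   polygons: list[tuple[int, BaseGeometry]] | None = None,
                   ) -> dict[int, MatchCategory | None]:
    """Best category achieved for each reference crown.

    A crown is recovered when some segment captures it as Matched or Nearly
    matched; the returned mapping gives, per crown id, the best category of
    any segment whose dominant crown is that crown (None if untouched).
    """
    if polygons is None:
        polygons = polygonize_segments(segmap)
    order = {c: i for i, c in enumerate([
        MatchCategory.MATCHED, MatchCategory.NEARLY_MATCHED,
        MatchCategory.SPLIT, MatchCategory.MERGED_ONE_CLASS,
        MatchCategory.MERGED_MULTI_CLASS, MatchCategory.FRAGMENTED])}
    tree = STRtree([r.polygon for r in references])
    best: dict[int, MatchCategory | None] = {r.id: None for r in references}
    for sid, poly in polygons:
        nearby = [references[i] for i in tree.query(poly)]
        if not nearby or _is_background(poly, nearby):
            continue
        category = categorize_segment(poly, nearby, thresholds)
        overlaps = [(overlap_fraction(poly, r, thresholds.use_iou), r)
                    for r in nearby]
        o, dominant = max(overlaps, key=lambda t: t[0])
        if o <= 0:
            continue
        prev = best[dominant.id]
        if prev is None or order[category] < order[prev]:
            best[dominant.id] = category
    return best
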