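"""Island eligibility filters, artifact exclusion, merging and selection.

Two eligibility profiles are implemented, matching the two arms of the
analysis:

* ``dp`` — per-mark rules for the deep paired libraries: islands must be at
  least 800 bp (H3K27me3) or 400 bp (H3K4me3) long, carry more than 50 tags
  and exceed a tag/length density of 0.03 (H3K27me3) or 0.04 (H3K4me3).
* ``subsets`` — for the developmental-stage series: at least 800 bp, caller
  score above 45 and density above 0.04.

Merged regions with any of three artifact signatures are excluded from the
H3K27me3 analysis: short distal regions (<= 1.2 kb and > 5 kb from the
nearest TSS, likely sequencing noise), island "tails" (< 2 kb regions
within 5 kb of a >= 3x longer island), and input-enriched regions (input
density > 0.024).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import (
    BinnedTrack,
    GeneAnnotation,
    GenomicRegion,
    Island,
    MergedRegion,
    point_region_distance,
    region_gap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "merge_regions",
    "filter_eligible_dp",
    "filter_eligible_subsets",
    "exclude_artifacts",
    "select_tss_proximal",
    "DP_RULES",
]

#: per-mark (min length bp, min tags exclusive, min density exclusive)
DP_RULES = {
    "H3K27me3": (800, 50.0, 0.03),
    "H3K4me3": (400, 50.0, 0.04),
}

SUBSET_MIN_LENGTH = 800
SUBSET_MIN_SCORE = 45.0  # exclusive
SUBSET_MIN_DENSITY = 0.04  # exclusive

ARTIFACT_SMALL_DISTAL_MAX_LEN = 1200
ARTIFACT_TSS_DISTANCE = 5000  # exclusive: strictly farther is an artifact
ARTIFACT_TAIL_MAX_LEN = 2000  # exclusive: strictly shorter
ARTIFACT_TAIL_VICINITY = 5000  # exclusive: strictly closer
ARTIFACT_TAIL_LENGTH_RATIO = 3.0  # inclusive: neighbor >= 3x longer
ARTIFACT_INPUT_DENSITY = 0.024  # exclusive


def merge_regions(island_sets: list[list[Island]]) -> list[MergedRegion]:
    """Union-of-overlaps merged regions across samples.

    Transitive closure of >= 1 bp overlaps over all input islands; half-open
    abutment ([100,200) next to [200,300)) is *not* overlap. Output is
    sorted and non-overlapping; each merged region carries the sum of its
    member islands' tag counts per sample.
    """
    if not island_sets:
        raise ValueError("need at least one island set")
    all_islands = [isl for s in island_sets for isl in s]
    all_islands.sort(key=lambda i: (i.region.chrom, i.region.start, i.region.end))
    merged: list[MergedRegion] = []
    current: list[Island] = []

    def close(group: list[Island]) -> None:
        region = GenomicRegion(
            group[0].region.chrom,
            min(i.region.start for i in group),
            max(i.region.end for i in group),
        )
        counts: dict[str, float] = {}
        for i in group:
            counts[i.sample] = counts.get(i.sample, 0.0) + i.tag_count
        merged.append(MergedRegion(region, counts, list(group)))

    hull_end = None
    for isl in all_islands:
        if (
            current
            and isl.region.chrom == current[0].region.chrom
            and hull_end is not None
            and isl.region.start < hull_end
        ):
            current.append(isl)
            hull_end = max(hull_end, isl.region.end)
        else:
            if current:
                close(current)
            current = [isl]
            hull_end = isl.region.end
    if current:
        close(current)
    return merged


def filter_eligible_dp(islands: list[Island], mark: str | None = None) -> list[Island]:
    """Keep islands satisfying the per-mark eligibility rules.

    Length is inclusive at the minimum; tag count and density thresholds
    are strict. ``mark=None`` takes each island's own ``mark`` field.
    """
    kept = []
    for isl in islands:
        m = mark or isl.mark
        if m not in DP_RULES:
            raise ValueError(f"unknown mark {m!r}; expected one of {sorted(DP_RULES)}")
        min_len, min_tags, min_density = DP_RULES[m]
        if (
            isl.region.length >= min_len
            and isl.tag_count > min_tags
            and isl.density > min_density
        ):
            kept.append(isl)
    return kept


def filter_eligible_subsets(islands: list[Island]) -> list[Island]:
    """Keep islands >= 800 bp with caller score > 45 and density > 0.04.

    Islands without a caller score skip the score clause (logged once)
    rather than failing.
    """
    missing_scores = sum(1 for i in islands if i.score is None)
    if missing_scores:
        logger.warning(
            "filter_eligible_subsets: %d islands without a caller score; "
            "score clause skipped for them", missing_scores,
        )
    kept = []
    for isl in islands:
        if isl.region.length < SUBSET_MIN_LENGTH:
            continue
        if isl.score is not None and not isl.score > SUBSET_MIN_SCORE:
            continue
        if not isl.density > SUBSET_MIN_DENSITY:
            continue
        kept.append(isl)
    return kept


def _tss_distance(region: GenomicRegion, genes: list[GeneAnnotation]) -> int | None:
    dists = [
        point_region_distance(g.tss, region)
        for g in genes
        if g.chrom == region.chrom
    ]
    return min(dists) if dists else None


def exclude_artifacts(
    merged: list[MergedRegion],
    genes: list[GeneAnnotation],
    input_track: BinnedTrack | None = None,
    input_counts: dict[GenomicRegion, float] | None = None,
) -> tuple[list[MergedRegion], list[tuple[MergedRegion, str]]]:
    """Split merged regions into (kept, excluded-with-reason).

    Three artifact rules, any of which excludes a region:

    ``small_distal``  length <= 1.2 kb AND nearest-TSS distance > 5 kb
    ``tail``          length < 2 kb AND edge-to-edge gap < 5 kb to a region
                      >= 3x longer (judged against the *unfiltered* input
                      set, so a tail is recognized even if its neighbor is
                      itself excluded)
    ``high_input``    input normalized tag count / length > 0.024

    TSS distance is 0 when a TSS falls inside the region; distances are
    edge-to-edge in bp, strand-ignored. Input counts come from
    ``input_track`` (bp-weighted mass) or an explicit ``input_counts`` map.
    """
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    kept: list[MergedRegion] = []
    excluded: list[tuple[MergedRegion, str]] = []
    regions = [m.region for m in merged]
    for m in merged:
        reason = None
        if m.region.length <= ARTIFACT_SMALL_DISTAL_MAX_LEN:
            d = _tss_distance(m.region, genes)
            if d is None or d > ARTIFACT_TSS_DISTANCE:
                reason = "small_distal"
        if reason is None and m.region.length < ARTIFACT_TAIL_MAX_LEN:
            for other in regions:
                if other is m.region:
                    continue
                gap = region_gap(m.region, other)
                if (
                    gap is not None
                    and gap < ARTIFACT_TAIL_VICINITY
                    and other.length >= ARTIFACT_TAIL_LENGTH_RATIO * m.region.length
                ):
                    reason = "tail"
                    break
        if reason is None:
            density = None
            if input_counts is not None and m.region in input_counts:
                density = input_counts[m.region] / m.region.length
            elif input_track is not None:
                density = input_track.region_mass(m.region) / m.region.length
            if density is not None and density > ARTIFACT_INPUT_DENSITY:
                reason = "high_input"
        if reason is None:
            kept.append(m)
        else:
            excluded.append((m, reason))
    return kept, excluded


def select_tss_proximal(
    islands: list[Island], genes: list[GeneAnnotation]
) -> dict[str, Island]:
    """For each gene, the single most TSS-proximal island.

    Distance is from the island's nearest edge to the TSS (0 if the island
    spans the TSS). Ties are broken by larger tag count, then leftmost
    start.
    """
    out: dict[str, Island] = {}
    for g in genes:
        candidates = [i for i in islands if i.region.chrom == g.chrom]
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda i: (
                point_region_distance(g.tss, i.region),
                -i.tag_count,
                i.region.start,
            ),
        )
        out[g.gene_id] = best
    return out
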