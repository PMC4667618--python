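"""Genomic annotation, Venn partitioning and overlap statistics.

Promoters are the strand-oriented window from 10 kb upstream to 1 kb
downstream of the TSS (closed at both bounds); the rest of the gene beyond
the +1 kb position is gene body; everything else is intergenic. Promoter
takes precedence over gene body, and among competing genes the one with the
nearest TSS wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import log2

from .core import (
    GeneAnnotation,
    GenomicRegion,
    Island,
    MergedRegion,
    point_region_distance,
)
from .islands import merge_regions

__all__ = [
    "AnnotationLabel",
    "VennPartition",
    "annotate",
    "venn_partition",
    "overlap_percentage",
    "call_bivalent",
    "log2_fc_over_input",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
]

PROMOTER_UPSTREAM = 10_000  # bp upstream of TSS
PROMOTER_DOWNSTREAM = 1_000  # bp downstream of TSS


@dataclass(frozen=True)
class AnnotationLabel:
    label: str  # promoter | gene_body | intergenic
    gene_id: str | None = None


def _promoter_window(gene: GeneAnnotation) -> GenomicRegion:
    # closed interval [TSS-10kb, TSS+1kb], strand-oriented, as half-open
    if gene.strand == "+":
        lo = gene.tss - PROMOTER_UPSTREAM
        hi = gene.tss + PROMOTER_DOWNSTREAM
    else:
        lo = gene.tss - PROMOTER_DOWNSTREAM
        hi = gene.tss + PROMOTER_UPSTREAM
    return GenomicRegion(gene.chrom, max(0, lo), hi + 1)


def _body_window(gene: GeneAnnotation) -> GenomicRegion | None:
    # gene extent beyond the +1 kb downstream position
    if gene.strand == "+":
        lo, hi = gene.tss + PROMOTER_DOWNSTREAM + 1, gene.body_end
    else:
        lo, hi = gene.body_end, gene.tss - PROMOTER_DOWNSTREAM - 1
    if hi < lo:
        return None
    return GenomicRegion(gene.chrom, max(0, lo), hi + 1)


def annotate(region: GenomicRegion, genes: list[GeneAnnotation]) -> AnnotationLabel:
    """Label a region promoter / gene_body / intergenic.

    Promoter beats gene body; among genes whose windows the region
    overlaps, the gene with the nearest TSS is reported. Total function:
    every region gets exactly one label.
    """
    promoter_hits = []
    body_hits = []
    for g in genes:
        if g.chrom != region.chrom:
            continue
        d = point_region_distance(g.tss, region)
        if region.overlaps(_promoter_window(g)):
            promoter_hits.append((d, g.gene_id))
        else:
            body = _body_window(g)
            if body is not None and region.overlaps(body):
                body_hits.append((d, g.gene_id))
    if promoter_hits:
        return AnnotationLabel("promoter", min(promoter_hits)[1])
    if body_hits:
        return AnnotationLabel("gene_body", min(body_hits)[1])
    return AnnotationLabel("intergenic", None)


@dataclass
class VennPartition:
    """Counts of merged regions per combination of overlapping input sets."""

    set_names: tuple[str, ...]
    cells: dict[frozenset, int]
    memberships: list[tuple[GenomicRegion, frozenset]]

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def count(self, *names: str) -> int:
        """Exact-cell count: regions overlapped by exactly these sets."""
        return self.cells.get(frozenset(names), 0)

    def regions_in(self, *names: str, exact: bool = False) -> list[GenomicRegion]:
        want = frozenset(names)
        if exact:
            return [r for r, m in self.memberships if m == want]
        return [r for r, m in self.memberships if want <= m]


def venn_partition(named_sets: dict[str, list[GenomicRegion]]) -> VennPartition:
    """Partition the merged union of several region sets by membership.

    All sets are merged into union-of-overlaps regions; each merged region
    is assigned the subset of input sets overlapping it by >= 1 bp, and
    cell counts sum to the total number of merged regions.
    """
    if not named_sets:
        raise ValueError("need at least one named region set")
    as_islands = [
        [Island(r, 0.0, sample=name) for r in regions]
        for name, regions in named_sets.items()
    ]
    merged = merge_regions(as_islands)
    memberships = []
    cells: dict[frozenset, int] = {}
    for m in merged:
        who = frozenset(
            name
            for name, regions in named_sets.items()
            if any(m.region.overlaps(r) for r in regions)
        )
        memberships.append((m.region, who))
        cells[who] = cells.get(who, 0) + 1
    return VennPartition(tuple(named_sets), cells, memberships)


def overlap_percentage(shared_count: int, total_count: int, decimals: int = 1) -> float:
    """100 * shared/total, rounded half-up to ``decimals`` places."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= shared_count <= total_count:
        raise ValueError("shared_count must be in [0, total_count]")
    pct = Decimal(100) * Decimal(shared_count) / Decimal(total_count)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def call_bivalent(
    k27_islands: list[Island], k4_islands: list[Island]
) -> list[GenomicRegion]:
    """Merged regions carrying both H3K27me3 and H3K4me3 ('bivalent')."""
    part = venn_partition(
        {
            "H3K27me3": [i.region for i in k27_islands],
            "H3K4me3": [i.region for i in k4_islands],
        }
    )
    return part.regions_in("H3K27me3", "H3K4me3")


def log2_fc_over_input(
    signal_count: float, input_count: float, pseudocount: float = 1.0
) -> float:
    """Binding intensity as log2 fold change over input."""
    if signal_count < 0 or input_count < 0:
        raise ValueError("counts must be >= 0")
    return log2((signal_count + pseudocount) / (input_count + pseudocount))
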