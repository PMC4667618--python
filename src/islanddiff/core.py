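"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` (BED-native).
Any 1-based external dialect is converted at the I/O boundary, never inside
the pipeline. Chromosome names are taken verbatim; no ``chr`` prefix
normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicRegion",
    "TagRead",
    "TagLibrary",
    "GeneAnnotation",
    "BinnedTrack",
    "Island",
    "Peak",
    "MergedRegion",
    "region_overlap",
    "point_region_distance",
    "region_gap",
]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def region_overlap(a: GenomicRegion, b: GenomicRegion) -> int:
    """Number of base pairs shared by two regions (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def point_region_distance(pos: int, region: GenomicRegion) -> int:
    """Distance in bp from a point to the nearest base of a region.

    0 when the point lies inside ``[start, end)``; otherwise the gap to the
    closest covered base (``end - 1`` is the last covered base).
    """
    if pos < region.start:
        return region.start - pos
    if pos >= region.end:
        return pos - (region.end - 1)
    return 0


def region_gap(a: GenomicRegion, b: GenomicRegion) -> int | None:
    """Edge-to-edge gap in bp between two regions on the same chromosome.

    0 for overlapping or abutting regions; ``None`` across chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass(frozen=True)
class TagRead:
    """A sequenced tag reduced to its 5' position and strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"read position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def extent(self, length: int) -> GenomicRegion:
        """The genomic footprint of the raw read (``length`` bp, strand-wise).

        A plus-strand read covers ``[pos, pos + length)``; a minus-strand
        read has its 5' end at ``pos`` and extends leftward, covering
        ``[pos - length + 1, pos + 1)`` clipped at 0.
        """
        if self.strand == "+":
            return GenomicRegion(self.chrom, self.pos, self.pos + length)
        start = max(0, self.pos - length + 1)
        return GenomicRegion(self.chrom, start, self.pos + 1)


@dataclass
class TagLibrary:
    """A collection of single-position stranded reads with a declared size.

    ``library_size`` defaults to the number of reads; it can be declared
    larger (e.g. pre-filtering sequencing depth) for normalization purposes.
    """

    reads: list[TagRead]
    library_size: int | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def by_chrom(self) -> dict[str, list[TagRead]]:
        out: dict[str, list[TagRead]] = {}
        for r in self.reads:
            out.setdefault(r.chrom, []).append(r)
        return out


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its TSS, strand and transcript end."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.body_end <= self.tss:
            raise ValueError(
                f"{self.gene_id}: body_end must lie downstream of the TSS (+ strand)"
            )
        if self.strand == "-" and self.body_end >= self.tss:
            raise ValueError(
                f"{self.gene_id}: body_end must lie downstream of the TSS (- strand)"
            )

    @property
    def extent(self) -> GenomicRegion:
        lo, hi = sorted((self.tss, self.body_end))
        return GenomicRegion(self.chrom, lo, hi + 1)


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin densities (normalized tags per bin)."""

    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def region_mass(self, region: GenomicRegion) -> float:
        """bp-overlap-weighted sum of bin values over a region."""
        vals = self.values.get(region.chrom)
        if vals is None:
            return 0.0
        bs = self.bin_size
        first = region.start // bs
        last = min((region.end - 1) // bs, len(vals) - 1)
        total = 0.0
        for b in range(first, last + 1):
            if b >= len(vals):
                break
            ov = min(region.end, (b + 1) * bs) - max(region.start, b * bs)
            if ov > 0:
                total += vals[b] * ov / bs
        return total

    def flatten(self) -> np.ndarray:
        """All bin values as one vector (chromosomes in sorted name order)."""
        chroms = sorted(self.values)
        if not chroms:
            return np.empty(0)
        return np.concatenate([self.values[c] for c in chroms])


@dataclass(frozen=True)
class Island:
    """An enriched region with a tag count and an (optional) caller score.

    ``score`` is an opaque caller statistic consumed by downstream filters;
    ``None`` means the caller did not report one, which disables score-based
    filters rather than failing.
    """

    region: GenomicRegion
    tag_count: float
    score: float | None = None
    sample: str = ""
    mark: str = ""

    def __post_init__(self) -> None:
        if self.tag_count < 0:
            raise ValueError("tag_count must be >= 0")

    @property
    def density(self) -> float:
        """Tag number / island length, the caller-agnostic enrichment ratio."""
        return self.tag_count / self.region.length


@dataclass(frozen=True)
class Peak:
    """A sharp binding site with a single-bp summit."""

    region: GenomicRegion
    summit: int
    tag_count: float = 0.0
    p_value: float | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if not (self.region.start <= self.summit < self.region.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.region}"
            )


@dataclass
class MergedRegion:
    """Union-of-overlaps region across samples with per-sample tag counts."""

    region: GenomicRegion
    per_sample_counts: dict[str, float] = field(default_factory=dict)
    members: list[Island] = field(default_factory=list)

    def count(self, sample: str, default: float = 0.0) -> float:
        return self.per_sample_counts.get(sample, default)
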