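"""Read-level filtering, extension/binning, and normalization.

The repeat filter keeps unique reads whose overlap with any masked repeat
interval is at most 5 bp, computed on the raw read extent (36 bp default),
not the extended fragment. Coverage tracks extend reads strand-wise to the
fragment length, distribute bp-overlap-weighted mass into fixed bins, and
scale to tags per million. Pairwise WT/mutant normalization supports
10%-trimmed-mean scaling of the larger library and ordinary-least-squares
regression of the mutant on the wild type; multi-track normalization uses
the standard mean-of-order-statistics quantile transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .core import BinnedTrack, GenomicRegion, TagLibrary, TagRead

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatMask",
    "NormalizationModel",
    "PairNormalizer",
    "QuantileTrackNormalizer",
    "filter_reads",
    "extend_and_bin",
    "count_tags",
    "fit_pair_normalization",
    "apply_normalization",
    "quantile_normalize",
]

MAX_REPEAT_OVERLAP = 5  # bp; reads overlapping a repeat by more are dropped


@dataclass
class RepeatMask:
    """Repeat-element intervals by class (SINE/LINE/LTR/satellite)."""

    intervals: dict[str, list[GenomicRegion]] = field(default_factory=dict)

    @classmethod
    def from_regions(cls, regions) -> "RepeatMask":
        """Build from (class, region) pairs or bare regions."""
        out: dict[str, list[GenomicRegion]] = {}
        for item in regions:
            if isinstance(item, GenomicRegion):
                klass, region = "repeat", item
            else:
                klass, region = item
            out.setdefault(klass, []).append(region)
        for k in out:
            out[k].sort()
        return cls(out)

    def all_regions(self) -> list[GenomicRegion]:
        return [r for regs in self.intervals.values() for r in regs]

    def trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for r in self.all_regions():
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        return trees


def filter_reads(
    library: TagLibrary, repeat_mask: RepeatMask, read_length: int = 36
) -> TagLibrary:
    """Collapse duplicates and drop repeat-overlapping reads.

    Duplicates (same chrom, 5' position and strand) are collapsed to one
    read; a read is then removed if its raw ``read_length``-bp extent shares
    more than 5 bp with any masked interval. Idempotent.
    """
    trees = repeat_mask.trees()
    seen: set[tuple[str, int, str]] = set()
    kept: list[TagRead] = []
    for read in library.reads:
        key = (read.chrom, read.pos, read.strand)
        if key in seen:
            continue
        seen.add(key)
        tree = trees.get(read.chrom)
        if tree is not None:
            ext = read.extent(read_length)
            bad = any(
                min(ext.end, iv.end) - max(ext.start, iv.begin) > MAX_REPEAT_OVERLAP
                for iv in tree.overlap(ext.start, ext.end)
            )
            if bad:
                continue
        kept.append(read)
    return TagLibrary(kept, sample=library.sample)


def extend_and_bin(
    library: TagLibrary,
    chrom_sizes: dict[str, int],
    fragment_length: int = 200,
    bin_size: int = 25,
) -> BinnedTrack:
    """Extend reads to the fragment length and bin, in tags per million.

    Each read is extended strand-wise from its 5' end to ``fragment_length``
    bp and contributes its extended interval's bp-overlap to each bin; the
    track is then divided by ``library_size / 1e6``. Extensions past a
    chromosome end are clipped and logged. Total un-clipped mass equals
    ``n_reads * fragment_length / (library_size / 1e6)``.
    """
    values = {
        c: np.zeros(-(-n // bin_size)) for c, n in chrom_sizes.items()
    }
    clipped = 0
    for read in library.reads:
        frag = read.extent(fragment_length)
        size = chrom_sizes.get(read.chrom)
        if size is None:
            raise ValueError(f"read on unknown chromosome {read.chrom!r}")
        start, end = frag.start, frag.end
        if end > size:
            end = size
            clipped += 1
        if read.strand == "-" and read.pos - fragment_length + 1 < 0:
            clipped += 1  # leftward extension hit position 0
        vals = values[read.chrom]
        for b in range(start // bin_size, (end - 1) // bin_size + 1):
            ov = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
            vals[b] += ov
    if clipped:
        logger.info("extend_and_bin: clipped %d read extensions at chromosome ends", clipped)
    scale = library.library_size / 1e6
    for c in values:
        values[c] /= scale
    return BinnedTrack(bin_size, values)


def count_tags(
    source: TagLibrary | BinnedTrack,
    regions: list[GenomicRegion],
    fragment_length: int | None = None,
) -> np.ndarray:
    """Per-region tag counts (or bp-weighted track mass).

    For a :class:`TagLibrary`, the count is the number of reads whose
    (optionally ``fragment_length``-extended) footprint overlaps the region
    by >= 1 bp; with ``fragment_length=None`` reads count as single points.
    For a :class:`BinnedTrack`, the overlap-weighted bin mass is returned.
    """
    if isinstance(source, BinnedTrack):
        return np.array([source.region_mass(r) for r in regions])
    if fragment_length is None:
        by_chrom: dict[str, np.ndarray] = {}
        for chrom, reads in source.by_chrom().items():
            by_chrom[chrom] = np.sort(np.array([r.pos for r in reads]))
        out = np.zeros(len(regions))
        for i, reg in enumerate(regions):
            pos = by_chrom.get(reg.chrom)
            if pos is None:
                continue
            out[i] = np.searchsorted(pos, reg.end, "left") - np.searchsorted(
                pos, reg.start, "left"
            )
        return out
    # extended reads: overlap iff ext.start < reg.end and ext.end > reg.start
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, reads in source.by_chrom().items():
        exts = [r.extent(fragment_length) for r in reads]
        starts[chrom] = np.sort(np.array([e.start for e in exts]))
        ends[chrom] = np.sort(np.array([e.end for e in exts]))
    out = np.zeros(len(regions))
    for i, reg in enumerate(regions):
        if reg.chrom not in starts:
            continue
        n = len(starts[reg.chrom])
        n_start_after = n - np.searchsorted(starts[reg.chrom], reg.end, "left")
        n_end_before = np.searchsorted(ends[reg.chrom], reg.start, "right")
        out[i] = n - n_start_after - n_end_before
    return out


@dataclass
class NormalizationModel:
    """A fitted pairwise (or track) normalization.

    kind ``trimmed_mean``: multiply the larger library's counts by
    ``scale``; kind ``linear_regression``: map the non-reference counts
    through ``(x - intercept) / slope``; kind ``library_size``: divide by
    ``scale`` (library size in millions).
    """

    kind: str
    scale: float = 1.0
    slope: float = 1.0
    intercept: float = 0.0
    trim_fraction: float = 0.10
    apply_to: str = "b"  # which side of the pair the transform targets

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.kind in ("trimmed_mean", "library_size") and self.scale <= 0:
            raise ValueError("scale factor must be positive")

    def transform(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)
        if self.kind == "trimmed_mean":
            return counts * self.scale
        if self.kind == "linear_regression":
            return (counts - self.intercept) / self.slope
        if self.kind == "library_size":
            return counts / self.scale
        raise ValueError(f"unknown normalization kind {self.kind!r}")


def fit_pair_normalization(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    kind: str = "trimmed_mean",
    trim_fraction: float = 0.10,
) -> NormalizationModel:
    """Fit a pairwise normalization over identical regions.

    ``trimmed_mean``: scale = trimmedMean(smaller) / trimmedMean(larger),
    applied to the larger library only (the one with the greater total),
    with a symmetric count-based trim (floor rounding per tail).
    ``linear_regression``: ordinary least squares of b on a (a is the
    reference); b is normalized as ``(b - intercept) / slope``. A slope
    <= 0 marks a degenerate pair and raises.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired count vectors must have equal length")
    if kind == "trimmed_mean":
        ta = stats.trim_mean(a, trim_fraction) if len(a) else 0.0
        tb = stats.trim_mean(b, trim_fraction) if len(b) else 0.0
        if np.array_equal(a, b) or ta == tb:
            return NormalizationModel(kind, 1.0, trim_fraction=trim_fraction,
                                      apply_to="b")
        if a.sum() >= b.sum():
            larger, t_small, t_large, side = a, tb, ta, "a"
        else:
            larger, t_small, t_large, side = b, ta, tb, "b"
        if t_large == 0:
            raise ValueError("degenerate pair: trimmed mean of larger library is 0")
        return NormalizationModel(
            kind, scale=t_small / t_large, trim_fraction=trim_fraction,
            apply_to=side,
        )
    if kind == "linear_regression":
        if np.array_equal(a, b):
            return NormalizationModel(kind, slope=1.0, intercept=0.0)
        if np.all(a == a[0]):
            raise ValueError("degenerate pair: reference counts are constant")
        res = stats.linregress(a, b)
        if res.slope <= 0:
            raise ValueError(
                f"degenerate pair: regression slope {res.slope:.4g} <= 0"
            )
        return NormalizationModel(kind, slope=float(res.slope),
                                  intercept=float(res.intercept))
    if kind == "library_size":
        raise ValueError("library_size normalization is not pairwise; "
                         "use NormalizationModel('library_size', size/1e6)")
    raise ValueError(f"unknown normalization kind {kind!r}")


def apply_normalization(counts: np.ndarray, model: NormalizationModel) -> np.ndarray:
    return model.transform(counts)


def normalize_pair(
    counts_a: np.ndarray, counts_b: np.ndarray, kind: str = "trimmed_mean",
    trim_fraction: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit and apply in one step, returning the normalized (a, b) pair."""
    model = fit_pair_normalization(counts_a, counts_b, kind, trim_fraction)
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if model.kind == "trimmed_mean" and model.apply_to == "a":
        return model.transform(a), b
    return a, model.transform(b)


class PairNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around the pairwise normalization schemes.

    ``fit(reference, other)`` learns the transform; ``transform(other)``
    returns the normalized counts of the non-reference sample. For the
    trimmed-mean kind the transform is the identity when the reference is
    the larger library (only the larger side is rescaled).
    """

    def __init__(self, kind: str = "trimmed_mean", trim_fraction: float = 0.10):
        self.kind = kind
        self.trim_fraction = trim_fraction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        self.model_ = fit_pair_normalization(X, y, self.kind, self.trim_fraction)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).ravel()
        if self.model_.kind == "trimmed_mean" and self.model_.apply_to == "a":
            return X  # the *reference* was the larger library
        return self.model_.transform(X)


def quantile_normalize(tracks: list[BinnedTrack]) -> list[BinnedTrack]:
    """Quantile-normalize >= 2 binned tracks to a common distribution.

    The reference distribution is the mean of order statistics across
    tracks; after the transform all tracks have exactly identical sorted
    value vectors. Ties within a track are ranked in stable positional
    order (so equal inputs may map to adjacent reference values). Tracks
    must share bin size and per-chromosome bin layout.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs >= 2 tracks")
    bs = tracks[0].bin_size
    layout = {c: len(v) for c, v in tracks[0].values.items()}
    for t in tracks[1:]:
        if t.bin_size != bs or {c: len(v) for c, v in t.values.items()} != layout:
            raise ValueError("tracks must share bin size and bin layout")
    flat = np.vstack([t.flatten() for t in tracks])
    reference = np.sort(flat, axis=1).mean(axis=0)
    out_flat = np.empty_like(flat)
    for i, row in enumerate(flat):
        order = np.argsort(row, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(row))
        out_flat[i] = reference[ranks]
    chroms = sorted(layout)
    out = []
    for i, t in enumerate(tracks):
        vals = {}
        off = 0
        for c in chroms:
            n = layout[c]
            vals[c] = out_flat[i, off : off + n].copy()
            off += n
        out.append(BinnedTrack(bs, vals))
    return out


class QuantileTrackNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style facade over :func:`quantile_normalize`.

    ``fit_transform(tracks)`` takes and returns a list of
    :class:`BinnedTrack`; the fitted ``reference_`` holds the learned
    order-statistic distribution.
    """

    def fit(self, X, y=None):
        flat = np.vstack([t.flatten() for t in X])
        self.reference_ = np.sort(flat, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        return quantile_normalize(list(X))
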