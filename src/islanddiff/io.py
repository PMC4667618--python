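"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* BED3/BED6 intervals, plus two tab-delimited dialects:
  ``island_table`` (chrom, start, end, tag_count[, score]) and
  ``peak_table`` (chrom, start, end, summit, tag_count[, p_value]).
* fixed-step wiggle and bedGraph coverage tracks,
* FASTA (via Biopython),
* a minimal TSS table (gene_id, chrom, tss, strand, body_end),
* a tab-delimited expression matrix (probe_set, gene_id, one column per
  sample).

All interval records are validated into :class:`~islanddiff.core.GenomicRegion`
(0-based half-open) on read; malformed lines raise with their line number.
Comment/track/browser lines are skipped, counted, and logged — never
silently dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import BinnedTrack, GeneAnnotation, GenomicRegion, Island, Peak, TagRead, TagLibrary

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_tags",
    "write_tags",
    "write_track",
    "read_track",
    "read_fasta",
    "write_fasta",
    "read_tss_table",
    "write_tss_table",
    "read_expression",
    "write_expression",
]


class FormatError(ValueError):
    """A malformed record in an external file, tagged with its line number."""


def _data_lines(path: str | Path):
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                skipped += 1
                continue
            yield lineno, line
    if skipped:
        logger.info("%s: skipped %d comment/track/blank lines", path, skipped)


def _parse_region(fields: Sequence[str], path, lineno: int) -> GenomicRegion:
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    try:
        return GenomicRegion(fields[0], start, end)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_intervals(path: str | Path, format: str = "bed"):
    """Read an interval file into validated records, preserving line order.

    Parameters
    ----------
    path : path to a tab-delimited file.
    format : one of ``bed`` (-> GenomicRegion), ``island_table`` (-> Island),
        ``peak_table`` (-> Peak).
    """
    if format not in ("bed", "island_table", "peak_table"):
        raise ValueError(f"unknown interval format {format!r}")
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        region = _parse_region(fields, path, lineno)
        try:
            if format == "bed":
                records.append(region)
            elif format == "island_table":
                if len(fields) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: island_table needs >=4 columns"
                    )
                score = None
                if len(fields) >= 5 and fields[4] not in (".", "", "NA"):
                    score = float(fields[4])
                records.append(
                    Island(region, tag_count=float(fields[3]), score=score)
                )
            else:  # peak_table
                if len(fields) < 5:
                    raise FormatError(
                        f"{path}:{lineno}: peak_table needs >=5 columns"
                    )
                pval = None
                if len(fields) >= 6 and fields[5] not in (".", "", "NA"):
                    pval = float(fields[5])
                records.append(
                    Peak(
                        region,
                        summit=int(fields[3]),
                        tag_count=float(fields[4]),
                        p_value=pval,
                    )
                )
        except FormatError:
            raise
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_intervals(records: Iterable, path: str | Path, format: str = "bed") -> None:
    """Inverse of :func:`read_intervals` for the three dialects."""
    with open(path, "w") as fh:
        for rec in records:
            if format == "bed":
                r = rec
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            elif format == "island_table":
                r = rec.region
                score = "." if rec.score is None else repr(rec.score)
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{rec.tag_count!r}\t{score}\n")
            elif format == "peak_table":
                r = rec.region
                pval = "." if rec.p_value is None else repr(rec.p_value)
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{rec.summit}\t{rec.tag_count!r}\t{pval}\n"
                )
            else:
                raise ValueError(f"unknown interval format {format!r}")


def read_tags(path: str | Path, sample: str = "") -> TagLibrary:
    """Read a BED-like tag file (chrom, pos, pos+1, name, score, strand or
    chrom, pos, strand) into a :class:`TagLibrary`."""
    reads = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        try:
            if len(f) >= 6:  # BED6: 5' position depends on strand
                strand = f[5]
                pos = int(f[1]) if strand == "+" else int(f[2]) - 1
            elif len(f) == 3:
                pos, strand = int(f[1]), f[2]
            else:
                raise ValueError("expected 3 or >=6 columns")
            reads.append(TagRead(f[0], pos, strand))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return TagLibrary(reads, sample=sample)


def write_tags(library: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in library.reads:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\n")


def write_track(track: BinnedTrack, path: str | Path, format: str = "bedgraph") -> None:
    """Write a binned track as bedGraph or fixed-step wiggle.

    Bins are contiguous from position 0 per chromosome; values are printed
    with 6 significant digits.
    """
    if format not in ("bedgraph", "wig"):
        raise ValueError(f"unknown track format {format!r}")
    bs = track.bin_size
    with open(path, "w") as fh:
        if format == "bedgraph":
            fh.write(f'track type=bedGraph name="islanddiff" binsize={bs}\n')
            for chrom in sorted(track.values):
                for i, v in enumerate(track.values[chrom]):
                    fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v:.6g}\n")
        else:
            fh.write('track type=wiggle_0 name="islanddiff"\n')
            for chrom in sorted(track.values):
                fh.write(f"fixedStep chrom={chrom} start=1 step={bs} span={bs}\n")
                for v in track.values[chrom]:
                    fh.write(f"{v:.6g}\n")


def read_track(path: str | Path) -> BinnedTrack:
    """Read a bedGraph or fixed-step wiggle produced by :func:`write_track`.

    bedGraph intervals must be contiguous equal-width bins (mixed widths
    raise); wiggle must be fixedStep with span == step.
    """
    values: dict[str, list[float]] = {}
    bin_size: int | None = None
    chrom = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "browser")):
                continue
            if line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                step = int(kv["step"])
                if int(kv.get("span", step)) != step:
                    raise FormatError(f"{path}:{lineno}: span != step unsupported")
                if bin_size is None:
                    bin_size = step
                elif bin_size != step:
                    raise FormatError(f"{path}:{lineno}: mixed bin sizes")
                values.setdefault(chrom, [])
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) == 1:  # wiggle value line
                if chrom is None:
                    raise FormatError(f"{path}:{lineno}: value before fixedStep")
                values[chrom].append(float(f[0]))
            else:  # bedGraph
                c, start, end, v = f[0], int(f[1]), int(f[2]), float(f[3])
                width = end - start
                if bin_size is None:
                    bin_size = width
                elif width != bin_size:
                    raise FormatError(f"{path}:{lineno}: mixed bin sizes")
                vals = values.setdefault(c, [])
                if start != len(vals) * bin_size:
                    raise FormatError(f"{path}:{lineno}: non-contiguous bins")
                vals.append(v)
    if bin_size is None:
        raise FormatError(f"{path}: no track data")
    return BinnedTrack(bin_size, {c: np.array(v) for c, v in values.items()})


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: upper-cased sequence}; duplicate names raise."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence identifier {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_TSS_COLS = ["gene_id", "chrom", "tss", "strand", "body_end"]


def read_tss_table(path: str | Path) -> list[GeneAnnotation]:
    """Read the tab-delimited TSS table; duplicate gene ids raise."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if f[:5] == _TSS_COLS:  # optional header
            continue
        if len(f) < 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        if f[0] in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {f[0]!r}")
        seen.add(f[0])
        try:
            genes.append(GeneAnnotation(f[0], f[1], int(f[2]), f[3], int(f[4])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_tss_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSS_COLS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.body_end}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probe-set expression matrix.

    Returns a DataFrame indexed by ``probe_set`` with a ``gene_id`` column
    and one float column per sample. Duplicate probe-set ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_set": str, "gene_id": str})
    if "probe_set" not in df.columns or "gene_id" not in df.columns:
        raise FormatError(f"{path}: expression table needs probe_set and gene_id columns")
    if df["probe_set"].duplicated().any():
        dup = df.loc[df["probe_set"].duplicated(), "probe_set"].iloc[0]
        raise FormatError(f"{path}: duplicate probe_set {dup!r}")
    return df.set_index("probe_set")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="probe_set")
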