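"""Synthetic paired WT/mutant ChIP-seq data with planted ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: broad enriched islands over a Poisson background, a paired mutant
library whose per-island emission rate is scaled by a true fold change
(straddling the 1.8x call threshold), repeat-element intervals, peak summits
with planted GGGA/GGAA-style motifs in the surrounding sequence, and a
probe-set expression matrix coupled to the truly decreased islands.

Emission model: reads are single 5' positions drawn per-bp Poisson with rate
``background_rate`` outside islands and ``background_rate * enrichment_fold
* sample_fc`` inside, where ``sample_fc`` is 1 for wild type and the
island's planted ``mutant_fc`` for the mutant. An ``input`` sample is pure
background. All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicRegion, Island, Peak, TagLibrary, TagRead
from . import io as iomod

__all__ = [
    "SimulationConfig",
    "Genome",
    "PlantedIsland",
    "GroundTruth",
    "simulate_genome",
    "simulate_tags",
    "emit_calls",
    "simulate_expression",
    "evaluate_recovery",
    "write_fixtures",
]

_REPEAT_CLASSES = ("SINE", "LINE", "LTR", "satellite")

# Ratio above which a planted island counts as truly changed, matching the
# fold-change threshold the differential caller uses.
_TRUE_CALL_THRESHOLD = 1.8


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic paired-library experiment.

    Defaults are chosen so that planted islands carry a few hundred expected
    tags (deep enough that a >1.8x change is unambiguous), mirroring the
    high-tag-count islands the differential analysis targets.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 500_000
    n_islands: int = 40
    island_length_range: tuple[int, int] = (2500, 4500)
    #: fraction of islands centered on a gene TSS (the rest are intergenic)
    genic_island_fraction: float = 0.5
    n_genes: int = 40
    gene_length: int = 8000
    background_rate: float = 0.02  # tags per bp, wild type, outside islands
    enrichment_fold: float = 10.0
    #: per-island mutant/WT true rate ratio, cycled over islands in placement
    #: order; 0.3 plants a clear decrease, 1.0 an unchanged island.
    mutant_fc: tuple[float, ...] = (0.3, 1.0)
    repeat_density: float = 0.05
    repeat_length: int = 300
    read_length: int = 36
    samples: tuple[str, ...] = ("WT", "mut")
    mutant_samples: tuple[str, ...] = ("mut",)
    #: relative sequencing depth per sample (unnamed samples default to 1.0)
    library_sizes: dict[str, float] = field(default_factory=dict)
    n_peaks: int = 20
    motif_plant: tuple[str, int, int] = ("GGAA", 8, 150)  # motif, count, window
    expr_coupling_prob: float = 0.88
    expr_shift_fold: float = 8.0
    expr_noise_sd: float = 0.15  # log2 units
    probe_sets_per_gene: tuple[int, int] = (1, 3)
    #: Gamma-Poisson over-dispersion (variance/mean - 1); 0 = pure Poisson
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rate <= 0 or self.enrichment_fold <= 0:
            raise ValueError("rates must be positive")
        if any(fc <= 0 for fc in np.atleast_1d(self.mutant_fc)):
            raise ValueError("mutant_fc values must be positive")
        if not 0 <= self.expr_coupling_prob <= 1:
            raise ValueError("expr_coupling_prob must be in [0, 1]")
        if not 0 <= self.repeat_density < 1:
            raise ValueError("repeat_density must be in [0, 1)")
        lo, hi = self.island_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid island_length_range")

    def depth(self, sample: str) -> float:
        return float(self.library_sizes.get(sample, 1.0))


@dataclass(frozen=True)
class PlantedIsland:
    region: GenomicRegion
    enrichment_fold: float
    mutant_fc: float
    gene_id: str | None  # None = intergenic

    @property
    def true_label(self) -> str:
        if 1.0 / self.mutant_fc > _TRUE_CALL_THRESHOLD:
            return "decreased"
        if self.mutant_fc > _TRUE_CALL_THRESHOLD:
            return "increased"
        return "unchanged"

    def rate(self, background_rate: float, is_mutant: bool) -> float:
        fc = self.mutant_fc if is_mutant else 1.0
        return background_rate * self.enrichment_fold * fc


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: list[GeneAnnotation]
    repeats: list[tuple[str, GenomicRegion]]  # (repeat class, interval)
    sequences: dict[str, str]
    islands: list[PlantedIsland]
    peak_summits: list[tuple[str, int]]


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    islands: list[PlantedIsland]
    motif_positions: list[tuple[str, int]]  # (chrom, motif start)
    #: gene_id -> True if the gene received a coupled expression increase
    expression_effects: dict[str, bool] = field(default_factory=dict)

    def labels(self) -> dict[GenomicRegion, str]:
        return {pl.region: pl.true_label for pl in self.islands}


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    lengths: list[int],
    occupied: dict[str, list[tuple[int, int]]],
    margin: int = 0,
    max_tries: int = 2000,
) -> list[GenomicRegion]:
    """Uniformly place intervals avoiding previously occupied space."""
    chroms = sorted(chrom_sizes)
    placed = []
    for L in lengths:
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            size = chrom_sizes[chrom]
            if size <= L:
                continue
            start = int(rng.integers(0, size - L))
            lo, hi = start - margin, start + L + margin
            if all(e <= lo or s >= hi for s, e in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((start, start + L))
                placed.append(GenomicRegion(chrom, start, start + L))
                break
        else:
            raise ValueError(
                "could not place all intervals: genome too small for the "
                "requested packing"
            )
    return placed


def simulate_genome(config: SimulationConfig) -> tuple[Genome, GroundTruth]:
    """Build the genome model: chromosomes, genes, repeats, sequence, and
    planted islands/summits with their ground truth.

    Genes never overlap; each planted island maps to exactly one gene (it
    covers the gene's TSS) or to intergenic space. Repeat intervals cover
    approximately ``repeat_density`` of the genome. Motifs are planted by
    replacing bases around each peak summit so coordinates stay fixed.
    """
    rng = _rng(config, 0)
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)
    }
    occupied: dict[str, list[tuple[int, int]]] = {}

    # genes, with a margin so islands planted at a TSS touch only one gene
    gene_regions = _place_nonoverlapping(
        rng, chrom_sizes, [config.gene_length] * config.n_genes, occupied,
        margin=max(config.island_length_range) // 2 + 500,
    )
    genes = []
    for i, reg in enumerate(gene_regions):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss, body_end = reg.start, reg.end - 1
        else:
            tss, body_end = reg.end - 1, reg.start
        genes.append(GeneAnnotation(f"gene{i:04d}", reg.chrom, tss, strand, body_end))

    # planted islands: alternate genic (centered on a TSS) and intergenic
    lo, hi = config.island_length_range
    fcs = list(np.atleast_1d(config.mutant_fc))
    islands: list[PlantedIsland] = []
    gene_pool = list(genes)
    rng.shuffle(gene_pool)  # type: ignore[arg-type]
    for i in range(config.n_islands):
        L = int(rng.integers(lo, hi + 1))
        fc = float(fcs[i % len(fcs)])
        gene_id = None
        if rng.random() < config.genic_island_fraction and gene_pool:
            g = gene_pool.pop()
            start = max(0, g.tss - L // 2)
            start = min(start, chrom_sizes[g.chrom] - L)
            region = GenomicRegion(g.chrom, start, start + L)
            gene_id = g.gene_id
        else:
            region = _place_nonoverlapping(rng, chrom_sizes, [L], occupied)[0]
        islands.append(PlantedIsland(region, config.enrichment_fold, fc, gene_id))

    # repeats fill repeat_density of the genome, uniformly, round-robin class
    repeats: list[tuple[str, GenomicRegion]] = []
    if config.repeat_density > 0:
        total = sum(chrom_sizes.values())
        n_rep = int(round(config.repeat_density * total / config.repeat_length))
        rep_occ: dict[str, list[tuple[int, int]]] = {}
        regs = _place_nonoverlapping(
            rng, chrom_sizes, [config.repeat_length] * n_rep, rep_occ
        )
        repeats = [
            (_REPEAT_CLASSES[i % len(_REPEAT_CLASSES)], r)
            for i, r in enumerate(regs)
        ]

    # random sequence, then peak summits with planted motifs
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        c: rng.choice(bases, size=n).tobytes().decode()
        for c, n in sorted(chrom_sizes.items())
    }
    motif, count, window = config.motif_plant
    summits: list[tuple[str, int]] = []
    motif_positions: list[tuple[str, int]] = []
    candidate_islands = [pl for pl in islands]
    for i in range(config.n_peaks):
        if i < len(candidate_islands):
            reg = candidate_islands[i].region
            summit = (reg.start + reg.end) // 2
            chrom = reg.chrom
        else:
            chrom = sorted(chrom_sizes)[int(rng.integers(config.n_chrom))]
            summit = int(rng.integers(window, chrom_sizes[chrom] - window))
        summits.append((chrom, summit))
        seq = list(sequences[chrom])
        taken: list[tuple[int, int]] = []
        tries = 0
        planted = 0
        while planted < count and tries < 200:
            tries += 1
            off = int(rng.integers(-window, window - len(motif) + 1))
            pos = summit + off
            if pos < 0 or pos + len(motif) > len(seq):
                continue
            if any(s < pos + len(motif) and pos < e for s, e in taken):
                continue
            seq[pos : pos + len(motif)] = list(motif)
            taken.append((pos, pos + len(motif)))
            motif_positions.append((chrom, pos))
            planted += 1
        sequences[chrom] = "".join(seq)

    genome = Genome(chrom_sizes, genes, repeats, sequences, islands, summits)
    return genome, GroundTruth(islands, motif_positions)


_SAMPLE_STREAM_BASE = 100


def simulate_tags(
    genome: Genome, config: SimulationConfig, sample: str
) -> TagLibrary:
    """Draw a tag library for one sample from the Poisson emission model.

    The expected tag count of an island is ``rate * length * depth`` where
    ``rate`` folds in the planted enrichment and, for mutant samples, the
    island's true fold change; ``input`` is pure background everywhere.
    Strands are assigned uniformly.
    """
    known = list(config.samples) + ["input"]
    if sample in known:
        stream = _SAMPLE_STREAM_BASE + known.index(sample)
    else:  # deterministic but name-dependent
        stream = _SAMPLE_STREAM_BASE + 50 + sum(map(ord, sample)) % 1000
    rng = _rng(config, stream)
    depth = config.depth(sample)
    is_mutant = sample in config.mutant_samples
    is_input = sample == "input"

    def draw(mean: float) -> int:
        if config.overdispersion > 0:
            # Gamma-Poisson with Var = mean * (1 + overdispersion)
            shape = mean / config.overdispersion
            lam = rng.gamma(shape, config.overdispersion)
            return int(rng.poisson(lam))
        return int(rng.poisson(mean))

    reads: list[TagRead] = []
    for chrom in sorted(genome.chrom_sizes):
        size = genome.chrom_sizes[chrom]
        n_bg = draw(config.background_rate * size * depth)
        pos = rng.integers(0, size, size=n_bg)
        strands = rng.random(n_bg) < 0.5
        reads.extend(
            TagRead(chrom, int(p), "+" if s else "-")
            for p, s in zip(pos, strands)
        )
        if is_input:
            continue
        for pl in genome.islands:
            if pl.region.chrom != chrom:
                continue
            extra = pl.rate(config.background_rate, is_mutant) - config.background_rate
            if extra <= 0:
                continue
            n_extra = draw(extra * pl.region.length * depth)
            pos = rng.integers(pl.region.start, pl.region.end, size=n_extra)
            strands = rng.random(n_extra) < 0.5
            reads.extend(
                TagRead(chrom, int(p), "+" if s else "-")
                for p, s in zip(pos, strands)
            )
    return TagLibrary(reads, sample=sample)


def emit_calls(
    genome: Genome, libraries: dict[str, TagLibrary]
) -> tuple[dict[str, list[Island]], list[Peak]]:
    """Realized island and peak calls, standing in for a caller's output.

    Islands are the planted intervals with tag counts recounted from the
    emitted library (reads as points) and a synthetic monotone score; peak
    summits are the planted motif-window centers.
    """
    from .tags import count_tags

    regions = [pl.region for pl in genome.islands]
    island_tables: dict[str, list[Island]] = {}
    for sample, lib in libraries.items():
        counts = count_tags(lib, regions)
        rows = []
        for pl, n in zip(genome.islands, counts):
            # opaque caller statistic, monotone in enrichment; scaled so
            # clearly enriched islands land well above background scores
            score = 10 * n / np.sqrt(pl.region.length)
            rows.append(
                Island(pl.region, tag_count=float(n), score=float(score),
                       sample=sample, mark="H3K27me3")
            )
        island_tables[sample] = rows
    peaks = []
    half = 200
    for chrom, summit in genome.peak_summits:
        size = genome.chrom_sizes[chrom]
        start = max(0, summit - half)
        end = min(size, summit + half + 1)
        peaks.append(Peak(GenomicRegion(chrom, start, end), summit=summit))
    return island_tables, peaks


def simulate_expression(
    genome: Genome, ground_truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Probe-set expression matrix coupled to truly decreased islands.

    Each gene gets 1-3 probe sets with lognormal baseline and log2-normal
    noise. A gene associated with a truly decreased island is flagged
    "coupled" with probability ``expr_coupling_prob``; coupled genes receive
    a mutant-over-WT shift drawn from [shift, 2*shift] so the max/min
    dynamic range clears a 4x filter. Effects are recorded in the ground
    truth. Columns are linear-scale, one per sample in ``config.samples``.
    """
    rng = _rng(config, 7)
    decreased_genes = {
        pl.gene_id
        for pl in ground_truth.islands
        if pl.gene_id is not None and pl.true_label == "decreased"
    }
    lo_ps, hi_ps = config.probe_sets_per_gene
    rows = []
    for g in genome.genes:
        coupled = g.gene_id in decreased_genes and rng.random() < config.expr_coupling_prob
        ground_truth.expression_effects[g.gene_id] = bool(coupled)
        shift = (
            config.expr_shift_fold * (1 + rng.random())
            if coupled
            else 1.0
        )
        base = float(2 ** rng.normal(6, 1.5))
        n_ps = int(rng.integers(lo_ps, hi_ps + 1))
        for p in range(n_ps):
            vals = {}
            for sample in config.samples:
                mean = base * (shift if sample in config.mutant_samples else 1.0)
                vals[sample] = mean * 2 ** rng.normal(0, config.expr_noise_sd)
            rows.append({"probe_set": f"{g.gene_id}_ps{p}", "gene_id": g.gene_id, **vals})
    return pd.DataFrame(rows).set_index("probe_set")


def evaluate_recovery(
    config: SimulationConfig, seeds: Sequence[int]
) -> dict[str, float]:
    """Run the differential pipeline over planted fixtures and score it.

    For each seed: simulate genome and paired libraries, emit island calls,
    pair-normalize WT/mutant counts (10% trimmed mean) and call >1.8x
    changes; compare against the planted labels. Returns pooled
    ``sensitivity`` (decreased islands recovered), ``false_positive_rate``
    (unchanged islands called changed) and the pooled counts.
    """
    from .differential import call_differential
    from .tags import normalize_pair

    tp = fn = fp = tn = 0
    for seed in seeds:
        cfg = dataclasses.replace(config, seed=int(seed))
        genome, truth = simulate_genome(cfg)
        libraries = {s: simulate_tags(genome, cfg, s) for s in cfg.samples}
        islands, _ = emit_calls(genome, libraries)
        wt_sample, mut_sample = cfg.samples[0], cfg.mutant_samples[0]
        wt = np.array([i.tag_count for i in islands[wt_sample]])
        mut = np.array([i.tag_count for i in islands[mut_sample]])
        nwt, nmut = normalize_pair(wt, mut, kind="trimmed_mean")
        calls = call_differential(
            [i.region for i in islands[wt_sample]], nwt, nmut
        )
        for call, planted in zip(calls, truth.islands):
            if planted.true_label == "decreased":
                if call.label == "decreased":
                    tp += 1
                else:
                    fn += 1
            elif planted.true_label == "unchanged":
                if call.label == "unchanged":
                    tn += 1
                else:
                    fp += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "false_positive_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "n_decreased": tp + fn,
        "n_unchanged": fp + tn,
    }


def write_fixtures(config: SimulationConfig, outdir: str | Path) -> Path:
    """Run the whole generator and write every fixture file to ``outdir``.

    Writes per-sample tag BEDs and island tables, a peak table, the genome
    FASTA, TSS table, repeat BED, expression matrix, and a tab-delimited
    ground-truth sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    libraries = {s: simulate_tags(genome, config, s) for s in config.samples}
    libraries["input"] = simulate_tags(genome, config, "input")
    islands, peaks = emit_calls(genome, libraries)
    expr = simulate_expression(genome, truth, config)

    for sample, lib in libraries.items():
        iomod.write_tags(lib, outdir / f"tags_{sample}.tsv")
    for sample, isl in islands.items():
        iomod.write_intervals(isl, outdir / f"islands_{sample}.tsv", "island_table")
    iomod.write_intervals(peaks, outdir / "peaks.tsv", "peak_table")
    iomod.write_fasta(genome.sequences, outdir / "genome.fa")
    iomod.write_tss_table(genome.genes, outdir / "tss.tsv")
    with open(outdir / "repeats.bed", "w") as fh:
        for cls, r in genome.repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{cls}\n")
    iomod.write_expression(expr, outdir / "expression.tsv")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\tenrichment_fold\tmutant_fc\ttrue_label\n")
        for pl in truth.islands:
            r = pl.region
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{pl.gene_id or '.'}\t"
                f"{pl.enrichment_fold}\t{pl.mutant_fc}\t{pl.true_label}\n"
            )
    return outdir
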