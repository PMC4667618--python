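# Methods

This note records the models, parameter choices and numerical decisions
behind `islanddiff`, in the order data flows through the pipeline.

## Coordinates and formats

All intervals are 0-based half-open `[start, end)` internally (BED-native);
1-based external dialects (fixed-step wiggle) are converted at the I/O
boundary and round-trip losslessly. Half-open abutment is *not* overlap:
`[100,200)` and `[200,300)` never merge. Chromosome names are used
verbatim — no `chr` prefix normalization — so mixed naming between inputs
is the caller's responsibility. Parsers never drop records silently;
comment/track lines are counted and logged, and malformed lines raise with
their line number. The island-table dialect is
`chrom, start, end, tag_count[, score]`; a missing caller score is a
sentinel that disables score-based filters (with a logged warning) rather
than failing, because broad-domain callers do not all emit one.

## Tag processing

Reads are reduced to 5′ position and strand. The repeat filter first
collapses duplicates (identical chrom/position/strand), then removes reads
whose *raw* extent — 36 bp by default, matching typical short single-end
sequencing — shares more than 5 bp with any masked repeat interval. The
overlap is judged on the raw read, not the extended fragment, because the
filter is defined on reads; this is a documented choice, and the read
length is a parameter. The filter is idempotent.

Coverage tracks extend each read strand-wise to the fragment length
(200 bp default; 300 bp supported for libraries with longer inserts) and
distribute bp-overlap-weighted mass into fixed bins (25 bp default,
200 bp for quantile-normalized browser tracks), then scale to tags per
million. Total un-clipped mass is exactly
`n_reads × fragment_length / (library_size/1e6)`; extensions past
chromosome ends are clipped and logged.

Pairwise normalization:

* **Trimmed mean** — scale factor `trimmedMean(smaller)/trimmedMean(larger)`
  applied to the larger library only (larger = greater total count). The
  trim is symmetric, dropping `floor(0.10 · n)` values from each tail
  (`scipy.stats.trim_mean`). Identical pairs are an exact identity.
* **Linear regression** — OLS of the mutant on the wild type (the wild
  type is the reference; the direction is a documented choice), with the
  mutant mapped through `(m − intercept)/slope`. A non-positive slope
  marks a degenerate pair and raises rather than silently inverting signs.
* **Quantile** — mean-of-order-statistics reference over ≥ 2 equal-layout
  tracks. Ties are ranked in stable positional order instead of being
  averaged, so the post-transform sorted vectors of all tracks are
  *exactly* identical — the defining contract of the transform here; the
  cost is that equal inputs can map to adjacent reference values.

The trimmed-mean and regression schemes are also exposed as a
scikit-learn-style `PairNormalizer` (fit/transform) and the quantile
transform as `QuantileTrackNormalizer`, so they compose with sklearn
pipelines; the module-level functions wrap the same code.

Note a structural property surfaced by the recovery experiments: when a
large fraction of islands is truly changed in one direction, *any* global
pairwise normalization absorbs part of the signal (the trimmed mean of the
mutant library is pulled down by the decreased islands, compressing true
ratios from 3.3× toward ~2.2× and pushing unchanged islands toward 1.5×).
The pipeline still clears its recovery targets comfortably, but users
analysing globally shifted conditions should prefer the regression scheme
on a set of regions believed mostly unchanged.

## Island filtering

Eligibility profiles are pure per-record predicates (so they commute):
`dp` keeps islands ≥ 800 bp (H3K27me3) / ≥ 400 bp (H3K4me3) with > 50 tags
and density > 0.03 / > 0.04; `subsets` keeps islands ≥ 800 bp with caller
score > 45 and density > 0.04. Length bounds are inclusive; tag, score and
density bounds are strict.

Artifact exclusion (H3K27me3 analysis only) removes merged regions that
are (a) ≤ 1.2 kb and > 5 kb from the nearest TSS — small distal islands
consistent with sequencing noise; (b) < 2 kb and within 5 kb
(edge-to-edge) of a ≥ 3× longer island — "tails" of a neighbouring domain
picked up as separate calls; or (c) of input tag/length density > 0.024 —
input-enriched regions. Decisions taken where the rules are underspecified:
the tail rule is judged against the *unfiltered* merged set (a tail is a
tail even if its neighbour is itself excluded); distances are edge-to-edge
in bp, strand-ignored, with distance 0 when a TSS falls inside the region;
rules are tested in the order small-distal → tail → input, and each
exclusion carries the first rule it triggered. Kept and excluded sets
partition the input exactly.

Per-gene island selection minimizes the edge-to-TSS distance (0 for
spanning islands), breaking ties by larger tag count and then leftmost
start, so the selection is deterministic.

## Differential analysis

The fold change is computed on pseudocounted counts (default pseudocount 1
on the raw-count scale — the pipeline's count arithmetic has no variance
model, so the pseudocount only guards the zero-count limit). Thresholds
are strict: 1.8× for differential calls and 4× for the expression
dynamic-range filter. Calls are antisymmetric by construction: swapping
the pair maps decreased ↔ increased. Whether the 1.8× threshold applies
to counts or to length-scaled densities is exposed as a flag
(`use_density`); the two agree whenever regions are compared against
themselves across samples (identical lengths), which is the pipeline's
normal mode.

k-means clustering of tag-density or expression matrices row-standardizes
(mean 0, SD 1; constant rows map to zeros), then runs Euclidean k-means
with 25 restarts under a fixed seed (scikit-learn), keeping the
lowest-WCSS assignment. Probe-set selection for multi-probe genes takes
the highest expression × fold-change product, ties to the first
identifier. ChIP-qPCR helpers implement percent-input
`(ab − IgG)/1% input` and the H3-normalized ratio
`(K27 − IgG)/(H3 − IgG)`, clamping negative background-subtracted signal
to zero.

## Annotation and co-localization

Promoters are the strand-oriented closed window −10 kb … +1 kb around the
TSS; the remaining gene extent beyond +1 kb is gene body; everything else
is intergenic. Promoter beats gene body; among competing genes the
nearest TSS wins. The three labels are a total partition — every region
gets exactly one. Venn partitioning merges all input sets into
union-of-overlap regions and assigns each region the subset of inputs
overlapping it; cell counts sum to the number of merged regions and obey
inclusion–exclusion. Printed-percentage reproduction uses half-up decimal
rounding (`overlap_percentage`), matching how such percentages are
conventionally printed.

## Motif statistic

Motif counts over ±150 bp summit windows include overlapping occurrences
(GGGAA contains both a GGGA and a GGAA) and cover both strands by using a
complement-closed motif set rather than reverse-complementing sequences.
The null shuffles each window's bases uniformly (composition preserved
exactly) 100 times by default, with a mandatory seed.

The χ² construction was a genuinely open choice, and measurement settled
it: the pooled one-cell goodness-of-fit `(obs − exp)²/exp` (1 df) assumes
the motif total is Poisson, but clumping between GGGA and GGAA (and
TTCC/TCCC) makes window counts overdispersed by a factor ≈ 1.2, which
inflates the empirical size of that test to ≈ 0.078 at nominal α = 0.05.
The default construction therefore divides the squared deviation by the
permutation-estimated variance of the total,
`Σ_w Var(c_w) · (1 + 1/m)` (the `1/m` term covers the noise of the
estimated expectation), giving a χ²(1) statistic whose measured size is
≈ 0.05 over thousands of null replicates. The pooled one-cell form remains
available (`construction="pooled"`, and directly as `chi2_enrichment`).
Power is unaffected in practice: one planted GGAA per G-poor 301-bp window
over 200 windows is rejected at p ≪ 0.01.

The consensus-core scanner matches `AGGAA[AG]` (and its reverse
complement `[CT]TTCCT`) within ±40 bp of the summit, reporting
per-window offsets and strands.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes —
not raw sequencing. Reads are single 5′ positions drawn per-bp Poisson:
rate `background_rate` (default 0.02 tags/bp) outside islands and
`background_rate × enrichment_fold × sample_fc` inside, with
`enrichment_fold = 10` and per-island `mutant_fc` cycling through
(0.3, 1.0) — a clear decrease and a null, straddling the 1.8× threshold
from both sides. Island lengths are uniform on 2.5–4.5 kb so expected
wild-type island tags are ≥ 500, the deep-count regime in which pure
fold-change calling is statistically meaningful; one replicate per
condition mirrors the single-replicate design the pipeline targets.
Poisson emission (not negative binomial) is the minimal model matching the
pipeline's count arithmetic; a Gamma–Poisson over-dispersion knob exists
but defaults to off. An `input` sample is pure background.

Genes (default 40 of 8 kb on 2 × 500 kb chromosomes) never overlap and are
placed with a margin so that an island centered on a TSS touches exactly
one gene; half the islands are genic, half intergenic. Repeat intervals
(default 5 % of the genome, 300 bp each, SINE/LINE/LTR/satellite classes
round-robin) provide targets for the read filter. Motifs are planted by
*replacing* bases within ±150 bp of each peak summit, so coordinates stay
fixed. Expression coupling: genes under a truly decreased island receive,
with probability 0.88, a mutant-over-WT shift drawn from [8×, 16×] on top
of log2-normal noise (SD 0.15), with 1–3 probe sets per gene — enough to
guarantee passage of the strict 4× dynamic-range filter for coupled genes.

Everything is deterministic under the config seed (per-stage and
per-sample substreams), and the full fixture set round-trips through the
package's own readers.

What the generator does **not** model — and hence what passing tests do
not establish about real data: fragment-size distributions, duplicate
reads, mappability and GC bias, over-dispersed biological replication,
caller-specific island boundary behaviour, and correlated motif background
beyond base composition. The recovery results certify the *arithmetic* of
the pipeline under its own assumptions, not caller or aligner behaviour.

## Problem sizes

Default verification sizes were chosen to keep every check statistically
meaningful at desk scale: oracle equivalence on 1,000 random islands;
recovery on 200 islands × 5 seeds (500 true decreases, 500 nulls); motif
size on 2,000 null replicates of 20 windows × 50 permutations; power on
200 planted windows. The acceptance script re-runs all of these from
scratch in well under a minute on one CPU.

## Known limitations

* Score-based filtering treats the caller score as opaque; no attempt is
  made to reproduce SICER's score definition.
* Fold-change calls carry no significance test, by design — the method is
  a thresholded ratio, and adding one would change the method.
* The artifact "tail" rule's `<5 kb` vicinity is edge-to-edge by choice;
  midpoint-based distances would classify a handful of borderline regions
  differently.
* Visual/manual island groupings used in heatmap figures are out of scope
  as automated calls; k-means plus the stated rule predicates are the
  reproducible part.
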