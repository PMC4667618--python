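# islanddiff

Differential analysis of broad histone-mark "islands" between paired
wild-type and mutant ChIP-seq libraries, built for the kind of study that
asks how a repressive chromatin mark (H3K27me3, deposited by PRC2) changes
when a transcription factor is impaired across developmental stages — and
whether those changes co-localize with the factor's binding sites, with
bivalent H3K4me3/H3K27me3 domains, and with expression changes of the
underlying genes.

It is aimed at computational biologists who already have island/peak calls
(from a broad-domain caller such as SICER and a sharp-peak caller such as
MACS) and want a tested, scriptable implementation of the downstream
arithmetic: tag filtering and normalization, island eligibility and
artifact filters, fold-change classification, annotation and
co-localization logic, expression integration, and a summit-centered motif
statistic. A synthetic-data generator with planted ground truth makes the
whole pipeline testable without any sequencing data.

## The model

**Differential call.** For a merged region with pair-normalized tag counts
$w$ (wild type) and $m$ (mutant) and pseudocount $c$ (default 1),

$$\mathrm{FC} = \frac{m + c}{w + c},$$

the region is *decreased* when $1/\mathrm{FC} > 1.8$, *increased* when
$\mathrm{FC} > 1.8$, and *unchanged* otherwise (strict inequalities). A
region counts as dynamically lost when it is decreased in at least one
developmental-stage pair.

**Pairwise normalization.** Either 10 % trimmed-mean scaling — the larger
library is multiplied by
$\bar{x}^{(0.1)}_{\text{smaller}}/\bar{x}^{(0.1)}_{\text{larger}}$ — or
ordinary least squares of the mutant counts on the wild-type counts,
$m' = (m - \hat\beta_0)/\hat\beta_1$. Coverage tracks can additionally be
quantile-normalized to a common mean-of-order-statistics distribution.

**Island filters.** Eligibility: length ≥ 800 bp (H3K27me3) or ≥ 400 bp
(H3K4me3), > 50 tags, tag/length density > 0.03 resp. 0.04; or, for the
stage-series profile, length ≥ 800 bp, caller score > 45, density > 0.04.
Artifact exclusion drops merged regions that are ≤ 1.2 kb and > 5 kb from
the nearest TSS, < 2 kb "tails" within 5 kb of a ≥ 3× longer island, or
regions whose input density exceeds 0.024.

**Motif statistic.** In ±150 bp windows around peak summits, occurrences
of GGGA/GGAA (and complements TCCC/TTCC) are counted, overlaps included,
and compared against per-window composition-preserving base permutations
with a $\chi^2$(1 df) statistic; see `docs/methods.md` for the calibrated
default construction.

## Worked example

```python
import numpy as np
from islanddiff import (SimulationConfig, simulate_genome, simulate_tags,
                        emit_calls, normalize_pair, call_differential,
                        motif_enrichment)

cfg = SimulationConfig(seed=1)                # 40 islands, half with fc 0.3
genome, truth = simulate_genome(cfg)
libs = {s: simulate_tags(genome, cfg, s) for s in cfg.samples}
islands, peaks = emit_calls(genome, libs)

wt = np.array([i.tag_count for i in islands["WT"]])
mut = np.array([i.tag_count for i in islands["mut"]])
nwt, nmut = normalize_pair(wt, mut, kind="trimmed_mean")
calls = call_differential([i.region for i in islands["WT"]], nwt, nmut)
n_dec = sum(c.label == "decreased" for c in calls)
n_planted = sum(pl.true_label == "decreased" for pl in truth.islands)
print(f"{len(calls)} islands: {n_dec} called decreased ({n_planted} planted)")

res = motif_enrichment(peaks, genome.sequences, seed=1)
print(f"motif density {res.observed_mean:.2f} observed vs "
      f"{res.null_mean:.2f} permuted per window "
      f"(chi2={res.chi2_statistic:.1f}, p={res.p_value:.2g})")
```

This prints:

```
40 islands: 20 called decreased (20 planted)
motif density 13.55 observed vs 4.99 permuted per window (chi2=268.9, p=1.9e-60)
```

All 20 islands planted with a true mutant/WT rate ratio of 0.3 are
recovered as decreased and none of the 20 unchanged islands is miscalled;
the planted GGAA motifs around the peak summits lift the observed motif
density to 13.6 per 301-bp window against a permutation expectation of
5.0, which the χ² test rejects decisively.

The same operations are available from the shell:

```bash
islanddiff simulate --seed 1 --outdir fx/
islanddiff diffcall --wt fx/islands_WT.tsv --mut fx/islands_mut.tsv --out calls.tsv
islanddiff motif-test --peaks fx/peaks.tsv --fasta fx/genome.fa --seed 1 --out motif.tsv
```

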