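"""Island eligibility cascade, artifact exclusion, merging, selection."""

import numpy as np
import pytest

from islanddiff import (
    BinnedTrack,
    GeneAnnotation,
    GenomicRegion,
    Island,
    MergedRegion,
    exclude_artifacts,
    filter_eligible_dp,
    filter_eligible_subsets,
    merge_regions,
    select_tss_proximal,
)
from islanddiff.core import point_region_distance, region_gap, region_overlap


def _isl(chrom, start, end, tags=100.0, score=None, sample="WT", mark="H3K27me3"):
    return Island(GenomicRegion(chrom, start, end), tags, score, sample, mark)


def _random_islands(rng, n, chrom_count=3, span=100_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        L = int(rng.integers(50, 4000))
        out.append(
            _isl(
                f"chr{rng.integers(1, chrom_count + 1)}", s, s + L,
                tags=float(rng.integers(0, 300)),
                score=float(rng.random() * 100),
            )
        )
    return out


class TestMergeRegions:
    def test_overlapping_pair_merges(self):
        merged = merge_regions([[_isl("chr1", 100, 200)], [_isl("chr1", 150, 250)]])
        assert [m.region for m in merged] == [GenomicRegion("chr1", 100, 250)]

    def test_halfopen_abutment_not_merged(self):
        merged = merge_regions([[_isl("chr1", 100, 200)], [_isl("chr1", 200, 300)]])
        assert len(merged) == 2

    def test_per_sample_counts_summed(self):
        merged = merge_regions(
            [[_isl("chr1", 0, 100, tags=10), _isl("chr1", 50, 150, tags=5)],
             [_isl("chr1", 120, 200, tags=7, sample="mut")]]
        )
        (m,) = merged
        assert m.per_sample_counts == {"WT": 15.0, "mut": 7.0}

    def test_idempotent_and_order_independent(self, rng):
        sets = [_random_islands(rng, 80), _random_islands(rng, 80)]
        a = merge_regions(sets)
        b = merge_regions(sets[::-1])
        assert [m.region for m in a] == [m.region for m in b]
        again = merge_regions([[Island(m.region, 0.0) for m in a]])
        assert [m.region for m in again] == [m.region for m in a]

    def test_matches_union_find_on_random_intervals(self, rng):
        """Merged hulls equal a brute-force union-find transitive closure."""
        islands = _random_islands(rng, 500)
        merged = merge_regions([islands])
        parent = list(range(len(islands)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(islands)):
            for j in range(i + 1, len(islands)):
                if region_overlap(islands[i].region, islands[j].region) >= 1:
                    parent[find(i)] = find(j)
        groups = {}
        for i, isl in enumerate(islands):
            groups.setdefault(find(i), []).append(isl.region)
        expected = sorted(
            GenomicRegion(rs[0].chrom, min(r.start for r in rs), max(r.end for r in rs))
            for rs in groups.values()
        )
        assert sorted(m.region for m in merged) == expected


class TestEligibilityFilters:
    def test_dp_boundary_kept(self):
        # length exactly 800, 51 tags, density 51/800 > 0.03 -> kept
        kept = filter_eligible_dp([_isl("chr1", 0, 800, tags=51)], "H3K27me3")
        assert len(kept) == 1

    def test_dp_50_tags_removed(self):
        assert filter_eligible_dp([_isl("chr1", 0, 800, tags=50)], "H3K27me3") == []

    def test_dp_density_strict(self):
        # 0.03 exactly is not > 0.03
        assert filter_eligible_dp([_isl("chr1", 0, 2000, tags=60)], "H3K27me3") == []

    def test_dp_k4_uses_400bp_and_004(self):
        kept = filter_eligible_dp([_isl("chr1", 0, 400, tags=51, mark="H3K4me3")],
                                  "H3K4me3")
        assert len(kept) == 1
        assert filter_eligible_dp([_isl("chr1", 0, 399, tags=51)], "H3K4me3") == []

    def test_unknown_mark_errors(self):
        with pytest.raises(ValueError, match="unknown mark"):
            filter_eligible_dp([_isl("chr1", 0, 1000)], "H3K9me3")

    def test_subsets_length_799_removed(self):
        assert filter_eligible_subsets([_isl("chr1", 0, 799, tags=100, score=50)]) == []

    def test_subsets_score_45_removed(self):
        assert filter_eligible_subsets([_isl("chr1", 0, 1000, tags=100, score=45.0)]) == []

    def test_subsets_missing_score_skips_clause(self, caplog):
        kept = filter_eligible_subsets([_isl("chr1", 0, 1000, tags=100, score=None)])
        assert len(kept) == 1

    @pytest.mark.parametrize("profile", ["dp", "subsets"])
    def test_matches_brute_force_rules(self, rng, profile):
        islands = _random_islands(rng, 400)
        if profile == "dp":
            got = filter_eligible_dp(islands, "H3K27me3")
            expected = [
                i for i in islands
                if i.region.length >= 800 and i.tag_count > 50
                and i.tag_count / i.region.length > 0.03
            ]
        else:
            got = filter_eligible_subsets(islands)
            expected = [
                i for i in islands
                if i.region.length >= 800 and i.score > 45
                and i.tag_count / i.region.length > 0.04
            ]
        assert got == expected


def _merged(chrom, start, end, counts=None):
    return MergedRegion(GenomicRegion(chrom, start, end), counts or {})


class TestExcludeArtifacts:
    genes = [GeneAnnotation("g1", "chr1", 50_000, "+", 60_000)]

    def test_1200bp_at_exactly_5kb_kept(self):
        # distance 5,000 is not > 5,000 -> not an artifact
        m = _merged("chr1", 43_801, 45_001)  # last base 45,000; TSS at 50,000
        assert point_region_distance(50_000, m.region) == 5000
        kept, excluded = exclude_artifacts([m], self.genes)
        assert excluded == [] and kept == [m]

    def test_small_distal_excluded(self):
        m = _merged("chr1", 30_000, 31_000)  # 1 kb region ~19 kb from TSS
        kept, excluded = exclude_artifacts([m], self.genes)
        assert kept == [] and excluded[0][1] == "small_distal"

    def test_tail_rule(self):
        tail = _merged("chr1", 50_000, 51_500)  # 1.5 kb
        big = _merged("chr1", 54_500, 59_000)  # 4.5 kb, 3 kb gap, 3x longer
        kept, excluded = exclude_artifacts([tail, big], self.genes)
        assert (tail, "tail") in excluded
        assert big in kept

    def test_tail_needs_3x_longer_neighbor(self):
        tail = _merged("chr1", 50_000, 51_500)
        big = _merged("chr1", 54_500, 58_900)  # 4.4 kb < 3 * 1.5 kb
        kept, _ = exclude_artifacts([tail, big], self.genes)
        assert tail in kept

    def test_high_input_rule(self):
        m = _merged("chr1", 49_000, 53_000)
        # flat input track: 0.1 normalized tags per 25 bp bin
        dense = BinnedTrack(25, {"chr1": np.full(4000, 25 * 0.03)})
        kept, excluded = exclude_artifacts([m], self.genes, input_track=dense)
        assert excluded[0][1] == "high_input"
        sparse = BinnedTrack(25, {"chr1": np.full(4000, 25 * 0.02)})
        kept, excluded = exclude_artifacts([m], self.genes, input_track=sparse)
        assert kept == [m]

    def test_partition_kept_plus_excluded(self, rng):
        merged = [
            _merged("chr1", s, s + int(rng.integers(400, 6000)))
            for s in rng.integers(0, 200_000, size=60)
        ]
        kept, excluded = exclude_artifacts(merged, self.genes)
        assert len(kept) + len(excluded) == len(merged)
        assert set(id(m) for m, _ in excluded).isdisjoint(id(m) for m in kept)

    def test_matches_brute_force_triple_rule_scan(self, rng):
        genes = [
            GeneAnnotation(f"g{i}", "chr1", int(t), "+", int(t) + 5000)
            for i, t in enumerate(sorted(rng.integers(0, 300_000, size=8)))
        ]
        merged = [
            _merged("chr1", int(s), int(s) + int(rng.integers(300, 7000)))
            for s in rng.integers(0, 300_000, size=120)
        ]
        input_counts = {
            m.region: float(rng.random() * 0.05 * m.region.length) for m in merged
        }
        kept, excluded = exclude_artifacts(
            merged, genes, input_counts=input_counts
        )
        regions = [m.region for m in merged]
        expected = {}
        for m in merged:
            r = m.region
            reason = None
            if r.length <= 1200 and min(
                point_region_distance(g.tss, r) for g in genes
            ) > 5000:
                reason = "small_distal"
            elif r.length < 2000 and any(
                o is not r and region_gap(r, o) < 5000 and o.length >= 3 * r.length
                for o in regions
            ):
                reason = "tail"
            elif input_counts[r] / r.length > 0.024:
                reason = "high_input"
            if reason:
                expected[r] = reason
        assert {m.region: why for m, why in excluded} == expected


class TestSelectTssProximal:
    genes = [
        GeneAnnotation("gA", "chr1", 10_000, "+", 20_000),
        GeneAnnotation("gB", "chr1", 80_000, "-", 70_000),
    ]

    def test_one_island_per_gene_identity(self):
        islands = [_isl("chr1", 9_000, 11_000), _isl("chr1", 79_000, 81_000)]
        sel = select_tss_proximal(islands, self.genes)
        assert sel == {"gA": islands[0], "gB": islands[1]}

    def test_spanning_island_beats_near_island(self):
        spanning = _isl("chr1", 9_500, 10_500)
        near = _isl("chr1", 10_100 + 100, 12_000)  # 200 bp away
        sel = select_tss_proximal([near, spanning], self.genes)
        assert sel["gA"] is spanning

    def test_tie_broken_by_tag_count_then_start(self):
        left = _isl("chr1", 9_000, 9_900, tags=10)  # 100 bp from TSS
        right = _isl("chr1", 10_100, 11_000, tags=50)  # 100 bp from TSS
        sel = select_tss_proximal([left, right], self.genes)
        assert sel["gA"] is right

    def test_matches_brute_force_per_gene(self, rng):
        islands = _random_islands(rng, 200, chrom_count=1, span=200_000)
        genes = [
            GeneAnnotation(f"g{i}", "chr1", int(t), "+", int(t) + 3000)
            for i, t in enumerate(rng.integers(0, 200_000, size=20))
        ]
        sel = select_tss_proximal(islands, genes)
        for g in genes:
            best = min(
                islands,
                key=lambda i: (
                    point_region_distance(g.tss, i.region),
                    -i.tag_count,
                    i.region.start,
                ),
            )
            assert sel[g.gene_id] == best
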