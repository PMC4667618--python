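"""Read filtering, extension/binning, counting and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from islanddiff import (
    BinnedTrack,
    GenomicRegion,
    PairNormalizer,
    RepeatMask,
    TagLibrary,
    TagRead,
    apply_normalization,
    count_tags,
    extend_and_bin,
    filter_reads,
    fit_pair_normalization,
    normalize_pair,
    quantile_normalize,
)
from islanddiff.core import region_overlap


def _lib(reads, **kw):
    return TagLibrary(list(reads), **kw)


class TestFilterReads:
    mask = RepeatMask.from_regions([("SINE", GenomicRegion("chr1", 100, 200))])

    def test_overlap_exactly_5bp_kept(self):
        # + read of 36 bp ending 5 bp into the repeat: [69, 105) & [100, 200)
        lib = _lib([TagRead("chr1", 69, "+")])
        assert len(filter_reads(lib, self.mask)) == 1

    def test_overlap_6bp_removed(self):
        lib = _lib([TagRead("chr1", 70, "+")])
        assert len(filter_reads(lib, self.mask)) == 0

    def test_minus_strand_extent_used(self):
        # - read 5' at 105 covers [70, 106): 6 bp overlap with repeat
        lib = _lib([TagRead("chr1", 105, "-")])
        assert len(filter_reads(lib, self.mask)) == 0

    def test_duplicates_collapsed(self):
        lib = _lib([TagRead("chr1", 10, "+")] * 3 + [TagRead("chr1", 10, "-")])
        assert len(filter_reads(lib, self.mask)) == 2

    def test_idempotent(self, small_world):
        genome, _, libraries, *_ = small_world
        mask = RepeatMask.from_regions(genome.repeats)
        once = filter_reads(libraries["WT"], mask)
        twice = filter_reads(once, mask)
        assert once.reads == twice.reads

    def test_matches_brute_force_scan(self, small_world):
        """Survivors equal a per-read brute-force overlap scan."""
        genome, _, libraries, *_ = small_world
        mask = RepeatMask.from_regions(genome.repeats)
        lib = libraries["WT"]
        got = {(r.chrom, r.pos, r.strand) for r in filter_reads(lib, mask).reads}
        expected = set()
        repeats = [r for _, r in genome.repeats]
        for read in lib.reads:
            ext = read.extent(36)
            if all(region_overlap(ext, rep) <= 5 for rep in repeats):
                expected.add((read.chrom, read.pos, read.strand))
        assert got == expected
        assert len(got) < len(lib.reads)  # the fixture plants real overlaps


class TestExtendAndBin:
    sizes = {"chr1": 1000}

    def test_plus_read_spreads_over_8_bins(self):
        lib = _lib([TagRead("chr1", 0, "+")])
        track = extend_and_bin(lib, self.sizes, fragment_length=200, bin_size=25)
        v = track.values["chr1"]
        # one read, library size 1 -> tags-per-million scale 1e6
        np.testing.assert_allclose(v[:8], 25 * 1e6)
        assert v[8:].sum() == 0

    def test_minus_read_extends_leftward(self):
        lib = _lib([TagRead("chr1", 399, "-")])
        track = extend_and_bin(lib, self.sizes, fragment_length=200, bin_size=25)
        v = track.values["chr1"]
        assert v[7] == 0 and v[8] > 0 and v[15] > 0 and v[16] == 0

    def test_clipping_at_chromosome_end(self):
        lib = _lib([TagRead("chr1", 950, "+")])
        track = extend_and_bin(lib, self.sizes, fragment_length=200, bin_size=25)
        assert track.values["chr1"].sum() == pytest.approx(50 * 1e6)

    def test_mass_conservation(self, small_world):
        """Total bin mass = n_reads * fragment_length / (libsize/1e6)."""
        genome, _, libraries, *_ = small_world
        lib = libraries["mut"]
        # keep reads away from edges so no clipping correction is needed
        inner = _lib(
            [r for r in lib.reads
             if 300 < r.pos < genome.chrom_sizes[r.chrom] - 300],
            library_size=lib.library_size,
        )
        track = extend_and_bin(inner, genome.chrom_sizes, 200, 25)
        expected = len(inner.reads) * 200 / (lib.library_size / 1e6)
        assert track.total_mass() == pytest.approx(expected, rel=1e-9)


class TestCountTags:
    def test_empty_regions(self):
        lib = _lib([TagRead("chr1", 5, "+")])
        assert count_tags(lib, []).size == 0

    def test_partition_conserves_total(self, small_world):
        genome, _, libraries, *_ = small_world
        lib = libraries["WT"]
        regions = [
            GenomicRegion(c, s, s + 50_000)
            for c, n in genome.chrom_sizes.items()
            for s in range(0, n, 50_000)
        ]
        assert count_tags(lib, regions).sum() == len(lib.reads)

    @pytest.mark.parametrize("fragment_length", [None, 200])
    def test_matches_nested_loop(self, rng, fragment_length):
        """Counts agree with an O(reads x regions) brute-force loop."""
        reads = [
            TagRead("chr1", int(rng.integers(0, 10_000)),
                    "+" if rng.random() < 0.5 else "-")
            for _ in range(1000)
        ]
        lib = _lib(reads)
        regions = []
        for _ in range(100):
            s = int(rng.integers(0, 9_900))
            regions.append(GenomicRegion("chr1", s, s + int(rng.integers(1, 400))))
        got = count_tags(lib, regions, fragment_length=fragment_length)
        for reg, g in zip(regions, got):
            if fragment_length is None:
                n = sum(reg.start <= r.pos < reg.end for r in reads)
            else:
                n = sum(
                    region_overlap(r.extent(fragment_length), reg) >= 1
                    for r in reads
                )
            assert g == n


class TestPairNormalization:
    def test_identity_on_identical_pairs(self, rng):
        x = rng.integers(0, 500, size=80).astype(float)
        for kind in ("trimmed_mean", "linear_regression"):
            model = fit_pair_normalization(x, x, kind)
            np.testing.assert_allclose(apply_normalization(x, model), x)

    def test_regression_recovers_doubling(self, rng):
        a = rng.integers(10, 500, size=60).astype(float)
        b = 2 * a
        model = fit_pair_normalization(a, b, "linear_regression")
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(apply_normalization(b, model), a)

    def test_trimmed_mean_scales_larger_library_only(self):
        a = np.array([10.0, 20, 30, 40, 50])
        b = 3 * a
        na, nb = normalize_pair(a, b, "trimmed_mean")
        np.testing.assert_allclose(na, a)  # smaller side untouched
        np.testing.assert_allclose(nb, a)  # larger side scaled down by 1/3

    def test_trimmed_mean_drops_outlier(self):
        """10% trim of {1..9, 1000} equals the sort-drop-mean brute force."""
        vals = np.array(list(range(1, 10)) + [1000], dtype=float)
        ref = np.full(10, 5.0)
        model = fit_pair_normalization(ref, vals, "trimmed_mean")
        dropped = np.sort(vals)[1:-1]  # floor(10 * 0.1) = 1 from each tail
        assert model.scale == pytest.approx(5.0 / dropped.mean())

    def test_negative_slope_errors(self):
        a = np.arange(1.0, 21)
        b = 100 - 4 * a
        with pytest.raises(ValueError, match="slope"):
            fit_pair_normalization(a, b, "linear_regression")

    def test_sklearn_wrapper_matches_functions(self, rng):
        a = rng.integers(0, 300, size=50).astype(float)
        b = rng.integers(0, 900, size=50).astype(float)
        est = PairNormalizer(kind="linear_regression").fit(a, b)
        model = fit_pair_normalization(a, b, "linear_regression")
        np.testing.assert_allclose(est.transform(b), model.transform(b))
        assert est.get_params()["kind"] == "linear_regression"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.integers(0, 1000), min_size=12, max_size=60),
        st.floats(0.5, 4.0),
    )
    def test_fit_apply_restores_scaled_pair(self, counts, factor):
        """Scaling one library by a constant is undone by both schemes."""
        a = np.asarray(counts, dtype=float)
        if np.all(a == a[0]):
            return  # degenerate constant vector
        b = factor * a
        na, nb = normalize_pair(a, b, "trimmed_mean")
        np.testing.assert_allclose(
            np.sort(na)[len(na) // 10 : -len(na) // 10 or None].mean(),
            np.sort(nb)[len(nb) // 10 : -len(nb) // 10 or None].mean(),
            rtol=1e-9,
        )
        model = fit_pair_normalization(a, b, "linear_regression")
        np.testing.assert_allclose(model.transform(b), a, atol=1e-6)


class TestQuantileNormalize:
    def test_identical_tracks_unchanged(self):
        t = BinnedTrack(200, {"chr1": np.array([1.0, 5.0, 2.0])})
        out = quantile_normalize([t, BinnedTrack(200, {"chr1": np.array([1.0, 5.0, 2.0])})])
        np.testing.assert_allclose(out[0].values["chr1"], [1, 5, 2])
        np.testing.assert_allclose(out[1].values["chr1"], [1, 5, 2])

    def test_closed_form_two_tracks(self):
        a = BinnedTrack(200, {"chr1": np.array([1.0, 2.0, 3.0])})
        b = BinnedTrack(200, {"chr1": np.array([4.0, 5.0, 6.0])})
        out = quantile_normalize([a, b])
        np.testing.assert_allclose(out[0].values["chr1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[1].values["chr1"], [2.5, 3.5, 4.5])

    def test_sorted_outputs_identical_across_tracks(self, rng):
        tracks = [
            BinnedTrack(200, {"chr1": rng.random(40) * rng.integers(1, 50),
                              "chr2": rng.random(15)})
            for _ in range(5)
        ]
        out = quantile_normalize(tracks)
        ref = np.sort(out[0].flatten())
        for t in out[1:]:
            np.testing.assert_array_equal(np.sort(t.flatten()), ref)

    def test_rank_order_preserved_within_track(self, rng):
        tracks = [BinnedTrack(25, {"chr1": rng.random(30)}) for _ in range(3)]
        out = quantile_normalize(tracks)
        for before, after in zip(tracks, out):
            assert (
                np.argsort(before.values["chr1"]).tolist()
                == np.argsort(after.values["chr1"]).tolist()
            )

    def test_mismatched_layout_errors(self):
        a = BinnedTrack(200, {"chr1": np.ones(3)})
        b = BinnedTrack(200, {"chr1": np.ones(4)})
        with pytest.raises(ValueError, match="layout"):
            quantile_normalize([a, b])
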