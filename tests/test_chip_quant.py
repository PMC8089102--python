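import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from superbiv.chip_quant import (
    ReadIndex,
    Window,
    bin_enrichment_matrix,
    count_reads_in_window,
    genome_bins,
    metagene_profile,
    promoter_enrichment_matrix,
    promoter_window,
    reads_to_midpoint_track,
    rpkm,
    track_window_sum,
)
from superbiv.io_formats import GeneModel, GenomeDef, ReadIntervals


def _reads(starts, length=50, mark="H3K4me3", sample="s1", chrom="chr1"):
    starts = np.asarray(starts, dtype=np.int64)
    return ReadIntervals(np.full(len(starts), chrom, dtype=object),
                         starts, starts + length, mark, sample)


def _random_reads(rng, n, genome_len, chrom="chr1"):
    starts = rng.integers(0, genome_len - 60, size=n)
    lengths = rng.integers(20, 60, size=n)
    return ReadIntervals(np.full(n, chrom, dtype=object), starts, starts + lengths,
                         "H3K4me3", "s1")


class TestMidpointCounting:
    def test_midpoint_inside_window_counts(self):
        reads = _reads([100])  # read (100,150), midpoint 125
        assert count_reads_in_window(reads, Window("chr1", 0, 200)) == 1

    def test_midpoint_outside_window_does_not_count(self):
        # read (190,250): midpoint 220 lies right of the window even though
        # the interval itself overlaps it
        reads = _reads([190], length=60)
        assert count_reads_in_window(reads, Window("chr1", 0, 200)) == 0

    def test_window_boundaries_are_half_open(self):
        reads = _reads([0, 175])  # midpoints 25 and 200
        assert count_reads_in_window(reads, Window("chr1", 25, 200)) == 1

    def test_unknown_chromosome_rejected(self):
        genome = GenomeDef(["chr1"], [1000])
        index = ReadIndex(_reads([10], length=20), genome)
        with pytest.raises(KeyError, match="unknown chromosome"):
            index.count(Window("chrX", 0, 100))

    def test_matches_bruteforce_scan_on_random_instances(self, rng):
        # independent oracle: per-read python loop on the midpoint rule
        for _ in range(10):
            genome_len = int(rng.integers(10_000, 1_000_000))
            reads = _random_reads(rng, int(rng.integers(100, 2000)), genome_len)
            index = ReadIndex(reads)
            mids = [(s + e) // 2 for s, e in zip(reads.start, reads.end)]
            for _ in range(5):
                a = int(rng.integers(0, genome_len - 1))
                b = int(rng.integers(a + 1, genome_len + 1))
                brute = sum(1 for m in mids if a <= m < b)
                assert index.count(Window("chr1", a, b)) == brute


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(10, 2000, 1_000_000) == 5.0
        assert rpkm(0, 2000, 1_000_000) == 0.0
        assert rpkm(329, 10_000, 20_000_000) == pytest.approx(1.645)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            rpkm(10, 1000, 0)
        with pytest.raises(ValueError, match="length"):
            rpkm(10, 0, 1000)

    @given(
        count=st.integers(0, 10_000),
        length=st.integers(1, 100_000),
        lib=st.integers(1, 10**8),
        scale=st.integers(2, 50),
    )
    def test_invariant_under_joint_scaling(self, count, length, lib, scale):
        assert rpkm(count * scale, length, lib * scale) == pytest.approx(
            rpkm(count, length, lib), rel=1e-12
        )


class TestPromoterMatrix:
    def test_window_clipped_at_chromosome_start(self):
        genome = GenomeDef(["chr1"], [1_000_000])
        gene = GeneModel("g1", "chr1", "+", 5000)
        w = promoter_window(gene, genome, 10_000)
        assert (w.start, w.end) == (0, 10_000)

    def test_clipped_length_used_for_rpkm(self):
        genome = GenomeDef(["chr1"], [6_000])
        gene = GeneModel("g1", "chr1", "+", 5000)  # window clips to (0, 6000)
        reads = _reads([1000], length=100)
        mat = promoter_enrichment_matrix([gene], {"s1": reads}, "H3K4me3", genome, 10_000)
        assert mat.values.loc["g1", "s1"] == pytest.approx(rpkm(1, 6000, 1))

    def test_zero_read_sample_gives_zero_column(self):
        genome = GenomeDef(["chr1"], [100_000])
        genes = [GeneModel("g1", "chr1", "+", 50_000)]
        empty = ReadIntervals.empty("H3K4me3", "s0")
        mat = promoter_enrichment_matrix(genes, {"s0": empty}, "H3K4me3", genome)
        assert (mat.values["s0"] == 0).all()

    def test_gene_on_unknown_chromosome_rejected(self):
        genome = GenomeDef(["chr1"], [100_000])
        genes = [GeneModel("g1", "chr2", "+", 50_000)]
        with pytest.raises(KeyError, match="unknown chromosome"):
            promoter_enrichment_matrix(genes, {}, "H3K4me3", genome)

    def test_housekeeping_exceeds_silent_on_synthetic_data(self, small_dataset, small_matrices):
        truth = small_dataset["truth"]
        col = small_matrices["H3K4me3_10kb"].sample("s1")
        hk = col.loc[sorted(truth.genes_of_class("housekeeping"))]
        silent = col.loc[sorted(truth.genes_of_class("silent"))]
        assert hk.min() > silent.max()


class TestGenomeBins:
    def test_last_bin_truncated(self):
        genome = GenomeDef(["chr1"], [25_000])
        bins = genome_bins(genome, 10_000)
        assert [(b.start, b.end) for b in bins] == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]

    def test_bin_count_is_ceiling_sum(self):
        genome = GenomeDef(["chr1", "chr2"], [25_000, 9_999])
        assert len(genome_bins(genome, 10_000)) == 3 + 1
        assert len(genome_bins(GenomeDef(["c"], [10]), 1)) == 10


class TestBinMatrix:
    def test_bin_counts_sum_to_library_size(self, rng):
        # the midpoint rule partitions the library across the tiling
        genome = GenomeDef(["chr1"], [100_000])
        reads = _random_reads(rng, 5_000, 100_000)
        index = ReadIndex(reads, genome)
        mat = bin_enrichment_matrix(genome, {"s1": index}, "H3K4me3", 10_000)
        lengths = np.array([w.length for w in mat.windows], dtype=float)
        counts = mat.values["s1"].to_numpy() * (lengths / 1e3) * (len(reads) / 1e6)
        assert np.round(counts.sum()) == len(reads)

    def test_identical_read_sets_give_identical_columns(self, rng):
        genome = GenomeDef(["chr1"], [50_000])
        starts = rng.integers(0, 49_000, size=500)
        a = _reads(starts, sample="a")
        b = _reads(starts, sample="b")
        mat = bin_enrichment_matrix(genome, {"a": a, "b": b}, "H3K4me3", 5_000)
        assert (mat.values["a"] == mat.values["b"]).all()

    def test_matches_bruteforce_per_bin_counts(self, rng):
        genome = GenomeDef(["chr1"], [100_000])
        reads = _random_reads(rng, 2_000, 100_000)
        mat = bin_enrichment_matrix(genome, {"s1": reads}, "H3K4me3", 7_000)
        mids = (reads.start + reads.end) // 2
        for w, rid in zip(mat.windows, mat.values.index):
            brute = int(((mids >= w.start) & (mids < w.end)).sum())
            assert mat.values.loc[rid, "s1"] == pytest.approx(
                rpkm(brute, w.length, len(reads))
            )


class TestMetageneProfile:
    def test_deterministic_uniform_coverage_gives_flat_profile(self):
        # one read midpoint per 10 bp everywhere -> every 100-bp bin holds the
        # same count, so the profile is exactly flat
        genome = GenomeDef(["chr1"], [40_000])
        starts = np.arange(0, 39_900, 10)
        reads = _reads(starts, length=20)
        gene = GeneModel("g1", "chr1", "+", 20_000)
        prof = metagene_profile([gene], reads, genome, hk_mean_rpkm=1.0)
        assert np.allclose(prof.values, prof.values[0])

    def test_housekeeping_self_normalisation_averages_to_one(self, small_dataset):
        d = small_dataset
        hk = [g for g in d["genes"] if g.is_housekeeping]
        mat = promoter_enrichment_matrix(hk, {"s1": d["k4"]}, "H3K4me3", d["genome"], 10_000)
        hk_mean = float(mat.values["s1"].mean())
        prof = metagene_profile(hk, d["k4"], d["genome"], hk_mean, label="housekeeping")
        assert prof.values.mean() == pytest.approx(1.0, abs=1e-9)

    def test_super_bivalent_profile_broader_than_bivalent(self, small_dataset):
        d = small_dataset
        truth = d["truth"]
        genes_by_id = {g.gene_id: g for g in d["genes"]}
        hk_ids = truth.housekeeping_ids
        mat = promoter_enrichment_matrix(
            [genes_by_id[g] for g in hk_ids], {"s1": d["k4"]}, "H3K4me3", d["genome"]
        )
        hk_mean = float(mat.values["s1"].mean())
        profs = {
            cls: metagene_profile(
                [genes_by_id[g] for g in sorted(truth.genes_of_class(cls))],
                d["k4"], d["genome"], hk_mean, label=cls,
            )
            for cls in ("super_bivalent", "bivalent")
        }
        assert profs["super_bivalent"].half_max_width() > profs["bivalent"].half_max_width()

    def test_minus_strand_profiles_are_reversed(self):
        genome = GenomeDef(["chr1"], [40_000])
        # asymmetric pile downstream of a minus-strand TSS (i.e. at lower coords)
        reads = _reads(np.full(100, 18_000), length=20)
        plus = GeneModel("gp", "chr1", "+", 20_000)
        minus = GeneModel("gm", "chr1", "-", 20_000)
        p_plus = metagene_profile([plus], reads, genome, 1.0)
        p_minus = metagene_profile([minus], reads, genome, 1.0)
        assert np.array_equal(p_plus.values[::-1], p_minus.values)

    def test_empty_subset_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            metagene_profile([], small_dataset["k4"], small_dataset["genome"], 1.0)


class TestBedGraphPileupPath:
    def test_track_window_sums_equal_read_window_counts(self, rng):
        # supplying reads pre-piled as a midpoint bedGraph must reproduce the
        # window counts of the raw-read path exactly
        genome = GenomeDef(["chr1"], [50_000])
        reads = _random_reads(rng, 1_000, 50_000)
        index = ReadIndex(reads, genome)
        track = reads_to_midpoint_track(index, genome)
        for _ in range(20):
            a = int(rng.integers(0, 49_000))
            b = int(rng.integers(a + 1, 50_001))
            w = Window("chr1", a, b)
            assert track_window_sum(track, w) == index.count(w)
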