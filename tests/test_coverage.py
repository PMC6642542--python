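import numpy as np
import pytest

from helpers_oracles import bruteforce_aligned_bases_in_region, bruteforce_pileup
from repviz import (
    CoverageError,
    CoverageTrack,
    GenomicRegion,
    ReadFilter,
    bin_track,
    compute_coverage,
    group_profiles,
    library_size,
    load_bam_config,
    make_group_profile,
    normalize_track,
    parse_region,
    write_bedgraph,
)
from repviz.fixtures import FixtureSpec, ReadSpec, random_fixture, write_bam


def _track(values, region=None, **kw):
    region = region or GenomicRegion("chr1", 0, len(values))
    return CoverageTrack(region, np.asarray(values), "t", **kw)


class TestComputeCoverage:
    def test_single_full_match_read(self, bam_factory):
        bam = bam_factory(FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 100, "10M"),)))
        track = compute_coverage(bam, parse_region("chr1:100-109"))
        assert track.values.tolist() == [1] * 10

    def test_spliced_read_skips_intron_bases(self, bam_factory):
        bam = bam_factory(FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 100, "5M3N5M"),)))
        track = compute_coverage(bam, parse_region("chr1:100-112"))
        assert track.values.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 1]

    def test_deletion_consumes_reference_without_depth(self, bam_factory):
        bam = bam_factory(FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 100, "4M2D4M"),)))
        track = compute_coverage(bam, parse_region("chr1:100-109"))
        assert track.values.tolist() == [1, 1, 1, 1, 0, 0, 1, 1, 1, 1]

    def test_soft_clips_and_insertions_add_nothing(self, bam_factory):
        bam = bam_factory(FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 100, "3S4M2I4M5S"),)))
        track = compute_coverage(bam, parse_region("chr1:98-110"))
        # 8 reference bases covered starting at 1-based 100
        assert track.values.tolist() == [0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_on_random_bams(self, bam_factory, seed):
        spec = random_fixture(seed, n_reads=200)
        bam = bam_factory(spec)
        region = GenomicRegion("chr1", 0, 2000)
        track = compute_coverage(bam, region)
        expected = bruteforce_pileup(spec.reads, region)
        np.testing.assert_array_equal(track.values, expected)
        # conservation: the track sums to the clipped aligned-base total
        assert int(track.values.sum()) == bruteforce_aligned_bases_in_region(
            spec.reads, region
        )

    def test_subregion_equals_slice_of_larger_region(self, bam_factory):
        spec = random_fixture(7, n_reads=200)
        bam = bam_factory(spec)
        full = compute_coverage(bam, GenomicRegion("chr1", 0, 2000))
        sub = compute_coverage(bam, GenomicRegion("chr1", 300, 900))
        np.testing.assert_array_equal(sub.values, full.values[300:900])

    def test_raising_min_mapq_never_increases_depth(self, bam_factory):
        spec = random_fixture(11, n_reads=200)
        bam = bam_factory(spec)
        region = GenomicRegion("chr1", 0, 2000)
        prev = compute_coverage(bam, region, ReadFilter(min_mapq=0)).values
        for mapq in (10, 30, 50, 61):
            cur = compute_coverage(bam, region, ReadFilter(min_mapq=mapq)).values
            assert (cur <= prev).all()
            np.testing.assert_array_equal(
                cur, bruteforce_pileup(spec.reads, region, min_mapq=mapq)
            )
            prev = cur

    def test_duplicate_exclusion_matches_oracle(self, bam_factory):
        spec = random_fixture(13, n_reads=200)
        bam = bam_factory(spec)
        region = GenomicRegion("chr1", 0, 2000)
        track = compute_coverage(bam, region, ReadFilter(exclude_duplicates=True))
        np.testing.assert_array_equal(
            track.values, bruteforce_pileup(spec.reads, region, exclude_duplicates=True)
        )

    def test_absent_chromosome_warns_and_returns_zero_track(self, bam_factory):
        bam = bam_factory(FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 1, "10M"),)))
        with pytest.warns(UserWarning, match="chr9"):
            track = compute_coverage(bam, GenomicRegion("chr9", 0, 50))
        assert track.values.tolist() == [0] * 50

    def test_missing_index_instructs_to_index(self, bam_factory, tmp_path):
        bam = bam_factory(FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 1, "10M"),)))
        (tmp_path / "fixture1.bam.bai").unlink()
        with pytest.raises(CoverageError, match="samtools index"):
            compute_coverage(bam, GenomicRegion("chr1", 0, 10))


class TestLibrarySize:
    def test_counts_primary_mapped_reads_only(self, bam_factory):
        reads = [ReadSpec("chr1", 1 + i, "20M") for i in range(95)]
        reads += [ReadSpec("chr1", 200 + i, "20M", secondary=True) for i in range(5)]
        bam = bam_factory(FixtureSpec((("chr1", 1000),), tuple(reads)))
        assert library_size(bam) == 95

    def test_random_flags_match_flag_counting_oracle(self, bam_factory):
        spec = random_fixture(3, n_reads=200)
        bam = bam_factory(spec)
        expected = sum(
            1 for r in spec.reads
            if not (r.unmapped or r.secondary or r.supplementary)
        )
        assert library_size(bam) == expected

    def test_unmapped_only_library_counts_zero(self, bam_factory):
        reads = tuple(ReadSpec("chr1", 5 + i, "10M", unmapped=True) for i in range(4))
        bam = bam_factory(FixtureSpec((("chr1", 1000),), reads))
        assert library_size(bam) == 0


class TestNormalizeAndBin:
    def test_cpm_arithmetic(self):
        out = normalize_track(_track([2, 4]), 2_000_000)
        assert out.values.tolist() == [1.0, 2.0]
        assert out.normalized

    def test_million_read_library_is_identity_scale(self):
        out = normalize_track(_track([5, 0, 7]), 1_000_000)
        assert out.values.tolist() == [5.0, 0.0, 7.0]

    def test_linearity_under_count_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 50, size=64)
        lib = 3_456_789
        for k in (2, 3, 7):
            lhs = normalize_track(_track(base * k), lib).values
            rhs = k * normalize_track(_track(base), lib).values
            np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_zero_library_rejected(self):
        with pytest.raises(CoverageError, match="library size"):
            normalize_track(_track([1]), 0)

    def test_binning_averages_and_partial_final_bin(self):
        assert bin_track(_track([0, 2, 4, 6]), 2).values.tolist() == [1.0, 5.0]
        assert bin_track(_track([3, 3, 3]), 2).values.tolist() == [3.0, 3.0]

    def test_bin_size_one_is_identity(self):
        track = _track([1, 2, 3])
        assert bin_track(track, 1) is track

    def test_width_weighted_sum_is_conserved(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 100, size=137)
        track = _track(values)
        for bin_size in (1, 2, 5, 7, 137, 500):
            binned = bin_track(track, bin_size)
            n = values.size
            widths = np.minimum(
                (np.arange(binned.values.size) + 1) * bin_size, n
            ) - np.arange(binned.values.size) * bin_size
            assert binned.values.size == -(-n // bin_size)
            np.testing.assert_allclose(
                float((binned.values * widths).sum()), float(values.sum())
            )

    def test_invalid_bin_size_rejected(self):
        with pytest.raises(CoverageError):
            bin_track(_track([1, 2]), 0)


class TestGroupProfiles:
    def test_mean_is_elementwise_average(self):
        region = GenomicRegion("chr1", 0, 3)
        t1 = CoverageTrack(region, np.array([0, 2, 4]), "a")
        t2 = CoverageTrack(region, np.array([2, 2, 0]), "b")
        prof = make_group_profile("g", [t1, t2])
        assert prof.mean_track.values.tolist() == [1.0, 2.0, 2.0]

    def test_single_replicate_mean_equals_replicate(self):
        track = _track([5, 1, 0, 9])
        prof = make_group_profile("solo", [track])
        np.testing.assert_array_equal(prof.mean_track.values, track.values)

    def test_unequal_group_sizes_each_average_over_own_size(self, tmp_path):
        region = GenomicRegion("chr1", 0, 2000)
        specs, rows = [], []
        for i in range(8):
            spec = random_fixture(100 + i, n_reads=60)
            write_bam(spec, tmp_path / f"s{i}.bam")
            specs.append(spec)
            rows.append(f"s{i}.bam,{'big' if i < 5 else 'small'}")
        cfg = tmp_path / "bams.csv"
        cfg.write_text("\n".join(rows) + "\n")
        profiles = group_profiles(load_bam_config(cfg), region)
        assert [len(p.replicate_tracks) for p in profiles] == [5, 3]
        for prof, chunk in zip(profiles, (specs[:5], specs[5:])):
            expected = np.mean(
                [bruteforce_pileup(s.reads, region) for s in chunk], axis=0
            )
            np.testing.assert_allclose(prof.mean_track.values, expected)
            stacked = np.stack([t.values for t in prof.replicate_tracks])
            assert (stacked.min(axis=0) <= prof.mean_track.values).all()
            assert (prof.mean_track.values <= stacked.max(axis=0)).all()

    def test_errors_are_tagged_with_sample_label(self, tmp_path):
        bam = write_bam(
            FixtureSpec((("chr1", 1000),), (ReadSpec("chr1", 1, "10M"),)),
            tmp_path / "weird.bam",
        )
        (tmp_path / "weird.bam.bai").unlink()
        cfg = tmp_path / "bams.csv"
        cfg.write_text("weird.bam,g\n")
        groups = load_bam_config(cfg, validate=False)
        with pytest.raises(CoverageError, match="weird"):
            group_profiles(groups, GenomicRegion("chr1", 0, 10))


class TestBedgraphExport:
    def test_runs_are_merged_and_tile_the_region(self, tmp_path):
        region = GenomicRegion("chr1", 10, 20)
        track = CoverageTrack(region, np.array([0, 0, 3, 3, 3, 1, 0, 0, 2, 2]), "s")
        out = write_bedgraph(track, tmp_path / "t.bedgraph")
        lines = out.read_text().strip().split("\n")
        assert lines == [
            "chr1\t10\t12\t0",
            "chr1\t12\t15\t3",
            "chr1\t15\t16\t1",
            "chr1\t16\t18\t0",
            "chr1\t18\t20\t2",
        ]
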