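import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakcoloc.intervals import (
    BedParseError,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    LayoutMismatchError,
    interval_length,
    merge_set,
    read_bed,
    read_chrom_sizes,
    resize_fixed_width,
    size_summary,
    write_bed,
)

HG19_LAYOUT = GenomeLayout({"chr1": 249_250_621})


class TestGenomicInterval:
    def test_printed_coordinate_length_is_813(self):
        iv = GenomicInterval("chr1", 7_507_615, 7_508_428)
        assert interval_length(iv) == 813

    @pytest.mark.parametrize(
        "start,end,expected",
        [(100, 101, 1), (0, 1000, 1000), (7_507_615, 7_508_428, 813)],
    )
    def test_length_examples(self, start, end, expected):
        assert GenomicInterval("chr1", start, end).length == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_inverted_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)

    def test_negative_start_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)

    def test_summit_offset_bounds(self):
        GenomicInterval("chr1", 100, 200, summit_offset=0)
        GenomicInterval("chr1", 100, 200, summit_offset=99)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 200, summit_offset=100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 200, summit_offset=-1)

    def test_midpoint_and_summit(self):
        iv = GenomicInterval("chr1", 100, 200, summit_offset=30)
        assert iv.midpoint == 150
        assert iv.summit == 130
        assert GenomicInterval("chr1", 100, 201).midpoint == 150


class TestGenomeLayout:
    def test_rejects_non_positive_lengths(self):
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})

    def test_total_bp(self, toy_layout):
        assert toy_layout.total_bp == 18_000


class TestIntervalSet:
    def test_sorted_per_chromosome(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 500, 600), ("chr1", 100, 200), ("chr2", 0, 50))
        starts = [iv.start for iv in s.intervals_on("chr1")]
        assert starts == [100, 500]
        assert len(s) == 3

    def test_rejects_unknown_chromosome(self, toy_layout):
        with pytest.raises(LayoutMismatchError):
            IntervalSet([GenomicInterval("chrX", 0, 10)], toy_layout)

    def test_rejects_out_of_bounds(self, toy_layout):
        with pytest.raises(ValueError):
            IntervalSet([GenomicInterval("chr1", 9_000, 11_000)], toy_layout)

    def test_covered_bp_counts_union(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 0, 100), ("chr1", 50, 150))
        assert s.covered_bp() == 150


class TestChromSizes:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t10000\nchr2\t8000\n")
        layout = read_chrom_sizes(p)
        assert layout.entries == {"chr1": 10_000, "chr2": 8_000}

    def test_bad_length(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\tNaN\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_chrom_sizes(p)

    def test_duplicate_chrom(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t100\nchr1\t200\n")
        with pytest.raises(BedParseError):
            read_chrom_sizes(p)


class TestReadBed:
    def test_paper_coordinate_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t7507615\t7508428\n")
        s = read_bed(p, HG19_LAYOUT)
        (iv,) = list(s)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 7_507_615, 7_508_428)
        assert iv.length == 813

    def test_empty_file(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p, toy_layout)) == 0

    def test_zero_length_is_parse_error(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p, toy_layout)

    def test_non_integer_coordinate(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t1e3\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p, toy_layout)

    def test_skips_track_browser_comment_lines(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text(
            "track name=x\nbrowser position chr1\n# comment\nchr1\t10\t20\n"
        )
        assert len(read_bed(p, toy_layout)) == 1

    def test_unknown_chrom_rejected_by_default(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t10\t20\n")
        with pytest.raises(BedParseError, match="chrZ"):
            read_bed(p, toy_layout)

    def test_unknown_chrom_drop_policy_warns(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t10\t20\nchr1\t10\t20\n")
        with pytest.warns(UserWarning, match="dropped 1"):
            s = read_bed(p, toy_layout, unknown_chrom="drop")
        assert len(s) == 1

    def test_narrowpeak_summit_column(self, tmp_path, toy_layout):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr1\t100\t200\tpeak1\t50\t.\t3.2\t5.1\t4.4\t30\n"
            "chr1\t300\t400\tpeak2\t10\t.\t1.0\t2.0\t1.5\t-1\n"
        )
        s = read_bed(p, toy_layout)
        ivs = list(s)
        assert ivs[0].summit_offset == 30
        assert ivs[1].summit_offset is None

    def test_bed6_fields(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tr1\t7.5\t+\n")
        (iv,) = list(read_bed(p, toy_layout))
        assert iv.name == "r1" and iv.score == 7.5 and iv.strand == "+"

    def test_write_read_round_trip(self, tmp_path, toy_layout, rng):
        from helpers import random_interval_set

        s = random_interval_set(rng, toy_layout, 50, names=True)
        p = tmp_path / "rt.bed"
        write_bed(s, p)
        s2 = read_bed(p, toy_layout)
        assert [(iv.chrom, iv.start, iv.end) for iv in s] == [
            (iv.chrom, iv.start, iv.end) for iv in s2
        ]


class TestMergeSet:
    def test_overlapping(self, toy_layout, mk):
        merged = merge_set(mk(toy_layout, ("chr1", 0, 100), ("chr1", 50, 150)))
        assert [(iv.start, iv.end) for iv in merged] == [(0, 150)]

    def test_book_ended_coalesce(self, toy_layout, mk):
        merged = merge_set(mk(toy_layout, ("chr1", 0, 100), ("chr1", 100, 200)))
        assert [(iv.start, iv.end) for iv in merged] == [(0, 200)]

    def test_disjoint_unchanged(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 0, 10), ("chr1", 20, 30))
        assert [(iv.start, iv.end) for iv in merge_set(s)] == [(0, 10), (20, 30)]

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=900),
                st.integers(min_value=1, max_value=100),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_merge_idempotent_and_coverage_preserving(self, raw):
        layout = GenomeLayout({"chr1": 1_000})
        s = IntervalSet(
            [GenomicInterval("chr1", a, a + w) for a, w in raw], layout
        )
        m1 = merge_set(s)
        m2 = merge_set(m1)
        assert list(m1) == list(m2)
        assert m1.covered_bp() == s.covered_bp()
        # merged intervals are disjoint with positive gaps
        ivs = list(m1)
        assert all(b.start > a.end for a, b in zip(ivs, ivs[1:]))


class TestResizeFixedWidth:
    def test_summit_centered(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 1000, 2000), summit_offset=300)
        out = resize_fixed_width(s, 300)
        assert [(iv.start, iv.end) for iv in out] == [(1000, 1600)]

    def test_midpoint_fallback(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 1000, 2000))
        out = resize_fixed_width(s, 300)
        assert [(iv.start, iv.end) for iv in out] == [(1200, 1800)]

    def test_clamped_at_chromosome_start(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 0, 100))
        out = resize_fixed_width(s, 300)
        assert [(iv.start, iv.end) for iv in out] == [(0, 350)]

    def test_flank_must_be_positive(self, toy_layout, mk):
        with pytest.raises(ValueError):
            resize_fixed_width(mk(toy_layout, ("chr1", 0, 100)), 0)

    def test_unclamped_regions_have_width_two_flank(self, toy_layout, rng):
        from helpers import random_interval_set

        s = random_interval_set(rng, toy_layout, 100)
        out = resize_fixed_width(s, 50)
        assert len(out) == len(s)
        for iv in out:
            clen = toy_layout.length_of(iv.chrom)
            if iv.start > 0 and iv.end < clen:
                assert iv.length == 100


class TestSizeSummary:
    def test_simple_lengths(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 0, 100), ("chr1", 200, 400), ("chr1", 500, 800))
        out = size_summary(s)
        assert out.mean == 200 and out.median == 200 and out.n == 3

    def test_single_region(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 0, 813))
        out = size_summary(s)
        assert out.mean == out.median == 813

    def test_even_count_median_is_mean_of_central_pair(self, toy_layout, mk):
        s = mk(toy_layout, ("chr1", 0, 100), ("chr1", 0, 200), ("chr1", 0, 300), ("chr1", 0, 1000))
        assert size_summary(s).median == 250

    def test_histogram_sums_to_n_and_fractions(self, toy_layout, rng):
        from helpers import random_interval_set

        s = random_interval_set(rng, toy_layout, 200, max_len=1500)
        out = size_summary(s, bin_width=100, thresholds=(1000, 500))
        assert sum(c for _, _, c in out.histogram) == out.n == 200
        assert all(0.0 <= f <= 1.0 for f in out.fraction_above.values())

    def test_empty_set_errors(self, toy_layout):
        with pytest.raises(ValueError):
            size_summary(IntervalSet([], toy_layout))

    def test_lognormal_fit_recovers_target_moments(self):
        # closed-form fit: sigma^2 = 2 ln(mean/median), mu = ln(median)
        mean_t, median_t = 1508.0, 1336.0
        mu = math.log(median_t)
        sigma = math.sqrt(2 * math.log(mean_t / median_t))
        draws = np.random.default_rng(42).lognormal(mu, sigma, size=100_000)
        assert abs(np.median(draws) - median_t) / median_t < 0.03
        assert abs(draws.mean() - mean_t) / mean_t < 0.03
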