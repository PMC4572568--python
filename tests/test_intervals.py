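import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from goshift.intervals import (
    AnnotationTrack,
    CoordinateError,
    GenomicInterval,
    gene_tracks,
    median_size,
    merge_track,
    positions_in_track,
    read_bed,
    read_gene_table,
    read_narrowpeak,
    summit_windows,
    tss_tes,
    union_tracks,
    write_bed,
)
from conftest import coverage_oracle, random_track


class TestMerge:
    def test_overlapping_intervals_union(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 15, 30)])
        assert [(iv.start, iv.end) for iv in merge_track(t)] == [(10, 30)]

    def test_different_chromosomes_untouched(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 10, 20), GenomicInterval("chr2", 10, 20)])
        merged = merge_track(t)
        assert [(iv.chrom, iv.start, iv.end) for iv in merged] == [
            ("chr1", 10, 20),
            ("chr2", 10, 20),
        ]

    def test_touching_intervals_merge(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 0, 5), GenomicInterval("chr1", 5, 10)])
        assert [(iv.start, iv.end) for iv in merge_track(t)] == [(0, 10)]

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(CoordinateError, match="start >= end"):
            GenomicInterval("chr1", 20, 10)

    def test_random_tracks_match_per_base_oracle(self):
        rng = np.random.default_rng(2)
        t = random_track(rng, 1000)
        merged = merge_track(t)
        oracle = coverage_oracle(t)
        assert sum(len(iv) for iv in merged) == int(oracle.sum())
        # merged intervals reproduce the oracle exactly, not just in total
        assert (coverage_oracle(merged) == oracle).all()
        # idempotence
        again = merge_track(merged)
        assert [(iv.start, iv.end) for iv in again] == [(iv.start, iv.end) for iv in merged]

    def test_merge_commutative_under_shuffle(self):
        rng = np.random.default_rng(3)
        t = random_track(rng, 50)
        shuffled = AnnotationTrack("t", list(rng.permutation(t.intervals)))
        assert [(iv.start, iv.end) for iv in merge_track(t)] == [
            (iv.start, iv.end) for iv in merge_track(shuffled)
        ]


class TestUnion:
    def test_self_union_idempotent(self):
        rng = np.random.default_rng(4)
        t = random_track(rng, 30)
        u = union_tracks([t, t])
        assert [(iv.start, iv.end) for iv in u] == [
            (iv.start, iv.end) for iv in merge_track(t)
        ]

    def test_adjacent_tracks_merge(self):
        a = AnnotationTrack("a", [GenomicInterval("chr1", 0, 5)])
        b = AnnotationTrack("b", [GenomicInterval("chr1", 5, 10)])
        assert [(iv.start, iv.end) for iv in union_tracks([a, b])] == [(0, 10)]

    def test_three_random_tracks_match_boolean_or(self):
        rng = np.random.default_rng(5)
        tracks = [random_track(rng, 200) for _ in range(3)]
        u = union_tracks(tracks)
        oracle = np.zeros(10_000, dtype=bool)
        for t in tracks:
            oracle |= coverage_oracle(t)
        assert (coverage_oracle(u) == oracle).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            union_tracks([])


class TestSummitWindows:
    def test_centered_window_width(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 300, 700, summit=500)])
        out = summit_windows(t, flank=100)
        assert [(iv.start, iv.end) for iv in out] == [(400, 601)]

    def test_clipped_at_origin(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 0, 200, summit=50)])
        out = summit_windows(t, flank=100)
        assert [(iv.start, iv.end) for iv in out] == [(0, 151)]

    def test_close_summits_merge(self):
        t = AnnotationTrack(
            "t",
            [
                GenomicInterval("chr1", 900, 1100, summit=1000),
                GenomicInterval("chr1", 1050, 1300, summit=1150),
            ],
        )
        out = summit_windows(t, flank=100)
        assert [(iv.start, iv.end) for iv in out] == [(900, 1251)]

    def test_missing_summit_identified(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 10, 20)])
        with pytest.raises(CoordinateError, match="chr1:10-20"):
            summit_windows(t)


class TestMedianSize:
    def test_odd_count(self):
        t = AnnotationTrack(
            "t",
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 20), GenomicInterval("chr3", 0, 30)],
        )
        assert median_size(t) == 20

    def test_even_count_lower_median(self):
        t = AnnotationTrack("t", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 20)])
        assert median_size(t) == 10

    def test_random_lengths_match_sort_oracle(self):
        rng = np.random.default_rng(6)
        lengths = rng.integers(1, 500, size=101)
        t = AnnotationTrack(
            "t", [GenomicInterval(f"chr{i}", 0, int(ln)) for i, ln in enumerate(lengths)]
        )
        assert median_size(t) == sorted(lengths)[50]

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            median_size(AnnotationTrack("t", []))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=30))
def test_merge_preserves_covered_bases(pairs):
    ivs = [GenomicInterval("chr1", s, s + ln) for s, ln in pairs]
    t = AnnotationTrack("t", ivs)
    oracle = np.zeros(600, dtype=bool)
    for s, ln in pairs:
        oracle[s : s + ln] = True
    assert sum(len(iv) for iv in merge_track(t)) == int(oracle.sum())


class TestReaders:
    def test_bed_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        t = merge_track(random_track(rng, 40))
        path = tmp_path / "t.bed"
        write_bed(t, path)
        back = read_bed(path)
        assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
            (iv.chrom, iv.start, iv.end) for iv in t
        ]

    def test_bed_bad_line_reports_position(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\nchr1\t30\t25\n")
        with pytest.raises(CoordinateError, match=":2"):
            read_bed(path)

    def test_narrowpeak_summit_offset(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text(
            "chr1\t100\t400\tpeak1\t0\t.\t5.0\t4.0\t3.0\t50\n"
            "chr1\t500\t700\tpeak2\t0\t.\t5.0\t4.0\t3.0\t-1\n"
        )
        t = read_narrowpeak(path)
        assert t.intervals[0].summit == 150
        assert t.intervals[1].summit is None


class TestGeneAnnotations:
    @pytest.fixture
    def genes(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "chrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname\n"
            "chr1\t+\t1000\t5000\t1000,3000\t1500,5000\tgA\n"
            "chr1\t-\t8000\t9000\t8000\t9000\tgB\n"
        )
        return read_gene_table(path)

    def test_promoters_are_strand_aware(self, genes):
        prom = gene_tracks(genes)["promoters"]
        assert [(iv.start, iv.end) for iv in prom] == [(500, 1000), (9000, 9500)]

    def test_exons_and_introns_partition_transcript(self, genes):
        tracks = gene_tracks(genes)
        exon_bases = sum(len(iv) for iv in tracks["exons"])
        intron_bases = sum(len(iv) for iv in tracks["introns"])
        gene_bases = sum(len(iv) for iv in tracks["genes"])
        assert exon_bases + intron_bases == gene_bases

    def test_tss_tes_strand_aware(self, genes):
        tt = tss_tes(genes).set_index("name")
        assert tt.loc["gA", "tss"] == 1000 and tt.loc["gA", "tes"] == 4999
        assert tt.loc["gB", "tss"] == 8999 and tt.loc["gB", "tes"] == 8000


def test_positions_in_track_matches_naive_scan():
    rng = np.random.default_rng(8)
    track = merge_track(random_track(rng, 100))
    pos = rng.integers(0, 10_000, size=500)
    chroms = np.array(["chr1"] * 500)
    got = positions_in_track(chroms, pos, track)
    naive = np.array(
        [any(iv.start <= p < iv.end for iv in track.intervals) for p in pos]
    )
    assert (got == naive).all()
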