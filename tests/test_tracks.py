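import numpy as np
import pytest

from ribostall import (
    PipelineConfig,
    assign_psite,
    build_track,
    filter_by_length,
    load_orfs,
    normalize_rpm,
)

from conftest import count_track, make_orf


@pytest.mark.parametrize(
    "length,kept",
    [(24, False), (25, True), (30, True), (34, True), (35, False)],
)
def test_footprint_length_window(length, kept):
    assert filter_by_length(length) is kept


def test_footprint_length_rejects_nonpositive():
    with pytest.raises(ValueError):
        filter_by_length(0)


@pytest.mark.parametrize(
    "pos,strand,expected",
    [(1000, "+", 982), (1000, "-", 1018), (10, "+", None)],
)
def test_psite_offset_from_three_prime_end(pos, strand, expected):
    assert assign_psite(pos, strand, 18) == expected


def test_rpm_normalization_values():
    t = count_track({"o": [5, 3, 0]}, total=1_000_000)
    rpm = normalize_rpm(t)
    assert rpm.rpm["o"].tolist() == [5.0, 3.0, 0.0]
    t2 = count_track({"o": [3, 0, 0]}, total=2_000_000)
    assert normalize_rpm(t2).rpm["o"][0] == 1.5


def test_rpm_requires_mapped_reads():
    t = count_track({"o": [0, 0, 0]}, total=0)
    with pytest.raises(ValueError, match="no mapped footprints"):
        normalize_rpm(t)


def test_rpm_depth_scale_invariance():
    t = count_track({"o": [4, 1, 7]}, total=100)
    doubled = count_track({"o": [8, 2, 14]}, total=200)
    np.testing.assert_allclose(normalize_rpm(t).rpm["o"], normalize_rpm(doubled).rpm["o"])


def _bedgraph(path, rows):
    path.write_text("".join(f"{c}\t{s}\t{e}\t{v}\n" for c, s, e, v in rows))
    return path


class TestBedgraphTracks:
    def test_counts_land_at_shifted_position(self, tmp_path):
        # ORF on + strand covering genomic 0..120; a 3'-end count of 7 at
        # genomic 100 must appear at ORF position 82 after the 18 nt shift
        orf = make_orf("o", "A" * 120)
        plus = _bedgraph(tmp_path / "p.bedgraph", [("chr1", 100, 101, 7)])
        track = build_track((plus, None), [orf], "treated", 1)
        assert track.counts["o"][82] == 7
        assert track.total_mapped == 7

    def test_minus_strand_shift_mirrors(self, tmp_path):
        orf = make_orf("o", "A" * 120, strand="-")
        # 3' end at genomic 10 -> P site at genomic 28 -> ORF index 120-1-28=91
        minus = _bedgraph(tmp_path / "m.bedgraph", [("chr1", 10, 11, 3)])
        track = build_track((None, minus), [orf], "treated", 1)
        assert track.counts["o"][91] == 3

    def test_contig_mismatch_is_error(self, tmp_path):
        orf = make_orf("o", "A" * 60)
        bad = _bedgraph(tmp_path / "b.bedgraph", [("chrX", 30, 31, 2)])
        with pytest.raises(ValueError, match="chrX"):
            build_track((bad, None), [orf], "treated", 1)

    def test_additivity_over_disjoint_read_sets(self, tmp_path):
        orf = make_orf("o", "A" * 120)
        a = _bedgraph(tmp_path / "a.bedgraph", [("chr1", 40, 41, 2)])
        b = _bedgraph(tmp_path / "b.bedgraph", [("chr1", 90, 91, 5)])
        both = _bedgraph(tmp_path / "ab.bedgraph", [("chr1", 40, 41, 2), ("chr1", 90, 91, 5)])
        ta = build_track((a, None), [orf], "treated", 1)
        tb = build_track((b, None), [orf], "treated", 1)
        tab = build_track((both, None), [orf], "treated", 1)
        combined = ta + tb
        np.testing.assert_array_equal(tab.counts["o"], combined.counts["o"])
        assert tab.total_mapped == combined.total_mapped

    def test_overlapping_orfs_each_count_total_counts_once(self, tmp_path):
        # two ORFs sharing genomic positions 30..60 on the same strand
        o1 = make_orf("o1", "A" * 60, start=0)
        o2 = make_orf("o2", "A" * 60, start=30)
        bg = _bedgraph(tmp_path / "x.bedgraph", [("chr1", 58, 59, 4)])  # P site 40
        track = build_track((bg, None), [o1, o2], "treated", 1)
        assert track.counts["o1"][40] == 4
        assert track.counts["o2"][10] == 4
        assert track.total_mapped == 4
        cfg = PipelineConfig(unique_orf=True)
        track_u = build_track((bg, None), [o1, o2], "treated", 1, config=cfg)
        assert track_u.total_mapped == 0

    def test_against_brute_force_oracle(self, tmp_path):
        """Every (read, ORF) pair enumerated independently must agree."""
        rng = np.random.default_rng(5)
        orfs = [
            make_orf("a", "A" * 90, start=0),
            make_orf("b", "A" * 60, start=50),
            make_orf("c", "A" * 60, start=200, strand="-"),
        ]
        reads = []  # (strand, 3'-end pos)
        for _ in range(100):
            if rng.random() < 0.7:
                reads.append(("+", int(rng.integers(0, 160))))
            else:
                reads.append(("-", int(rng.integers(150, 300))))
        plus = _bedgraph(
            tmp_path / "p.bedgraph",
            [("chr1", p, p + 1, 1) for s, p in reads if s == "+"],
        )
        minus = _bedgraph(
            tmp_path / "m.bedgraph",
            [("chr1", p, p + 1, 1) for s, p in reads if s == "-"],
        )
        track = build_track((plus, minus), orfs, "treated", 1)

        expected = {o.orf_id: np.zeros(len(o.nt_seq), dtype=int) for o in orfs}
        expected_total = 0
        for strand, end in reads:
            p = end - 18 if strand == "+" else end + 18
            hit = False
            for o in orfs:
                if o.strand != strand:
                    continue
                idx = o.genomic_to_orf(p)
                if idx is not None:
                    expected[o.orf_id][idx] += 1
                    hit = True
            expected_total += int(hit)
        for o in orfs:
            np.testing.assert_array_equal(track.counts[o.orf_id], expected[o.orf_id])
        assert track.total_mapped == expected_total


class TestSamTracks:
    def make_sam(self, tmp_path, rows):
        """rows: (name, flag, pos0, cigar, seqlen)"""
        sam = tmp_path / "reads.sam"
        lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:1000"]
        for name, flag, pos, cigar, seqlen in rows:
            lines.append(
                f"{name}\t{flag}\tchr1\t{pos + 1}\t42\t{cigar}\t*\t0\t0\t"
                f"{'A' * seqlen}\t{'I' * seqlen}"
            )
        sam.write_text("\n".join(lines) + "\n")
        return sam

    def test_plus_strand_read_counts_at_psite(self, tmp_path, genome_files):
        orfs = load_orfs(genome_files["fasta"], genome_files["gff3"])
        orf = make_orf("big", "A" * 300)
        # 28 nt read aligned at 100..127; 3' end 127 -> P site 109
        sam = self.make_sam(tmp_path, [("r1", 0, 100, "28M", 28)])
        track = build_track(sam, [orf], "treated", 1)
        assert track.counts["big"][109] == 1

    def test_length_filter_and_secondary_skipped(self, tmp_path):
        orf = make_orf("big", "A" * 300)
        sam = self.make_sam(
            tmp_path,
            [
                ("short", 0, 100, "24M", 24),  # below 25 nt
                ("sec", 256, 100, "28M", 28),  # secondary alignment
            ],
        )
        track = build_track(sam, [orf], "treated", 1)
        assert track.total_mapped == 0

    def test_soft_clips_excluded_from_three_prime_end(self, tmp_path):
        orf = make_orf("big", "A" * 300)
        # 4S26M: aligned span 100..126, footprint length 26, 3' end 125
        sam = self.make_sam(tmp_path, [("r1", 0, 100, "4S26M", 30)])
        track = build_track(sam, [orf], "treated", 1)
        assert track.counts["big"][125 - 18] == 1
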