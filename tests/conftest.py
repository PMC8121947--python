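import textwrap

import numpy as np
import pytest

from ribostall import OrfRecord, RpmTrack, SampleTrack


def make_orf(orf_id: str, nt_seq: str, chrom: str = "chr1", strand: str = "+", start: int = 0):
    """Single-exon ORF record without start/stop requirements (toy data)."""
    return OrfRecord(
        orf_id, chrom, strand, [(start, start + len(nt_seq))], nt_seq, check_edges=False
    )


@pytest.fixture
def toy_orf():
    # 30 nt / 10 codons: ATG + 8 sense codons + TAA
    return make_orf("toy", "ATG" + "AAA" * 8 + "TAA")


@pytest.fixture
def genome_files(tmp_path):
    """Tiny genome + GFF3 exercising plus/minus strands and splicing.

    orfA: + strand single exon ATG AAA TAA at 10..19
    orfB: - strand, genomic slice reverse-complements to ATG CCC TAA
    orfC: + strand two exons (6 nt + 3 nt) spliced to ATG AAA TAA
    """
    from ribostall.simulate import _revcomp

    plus_cds = "ATGAAATAA"
    chr1 = "G" * 10 + plus_cds + "C" * 10

    b_cds = "ATGCCCTAA"
    chr2 = "T" * 5 + _revcomp(b_cds) + "A" * 5  # CDS occupies 5..14 on minus strand
    c_exon1, c_exon2 = "ATGAAA", "TAA"
    chr3 = "A" * 4 + c_exon1 + "GGGGG" + c_exon2 + "T" * 4
    fasta = tmp_path / "genome.fa"
    fasta.write_text(
        f">chr1\n{chr1}\n>chr2\n{chr2}\n>chr3\n{chr3}\n"
    )
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        textwrap.dedent(
            """\
            ##gff-version 3
            chr1\tt\tmRNA\t11\t19\t.\t+\t.\tID=orfA
            chr1\tt\tCDS\t11\t19\t.\t+\t0\tID=cA;Parent=orfA
            chr2\tt\tmRNA\t6\t14\t.\t-\t.\tID=orfB
            chr2\tt\tCDS\t6\t14\t.\t-\t0\tID=cB;Parent=orfB
            chr3\tt\tmRNA\t5\t18\t.\t+\t.\tID=orfC
            chr3\tt\tCDS\t5\t10\t.\t+\t0\tID=cC1;Parent=orfC
            chr3\tt\tCDS\t16\t18\t.\t+\t0\tID=cC2;Parent=orfC
            """
        )
    )
    return {"fasta": fasta, "gff3": gff, "chr1": chr1, "chr2": chr2, "chr3": chr3}


def rpm_track(values_by_orf, sample_id="s", condition="treated", replicate=1, total=1_000_000):
    return RpmTrack(
        sample_id,
        condition,
        replicate,
        {k: np.asarray(v, dtype=float) for k, v in values_by_orf.items()},
        total,
    )


def count_track(values_by_orf, sample_id="s", condition="treated", replicate=1, total=None):
    counts = {k: np.asarray(v, dtype=np.int64) for k, v in values_by_orf.items()}
    if total is None:
        total = int(sum(v.sum() for v in counts.values()))
    return SampleTrack(sample_id, condition, replicate, counts, total)
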