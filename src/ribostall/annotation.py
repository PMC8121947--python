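"""Genome and ORF annotation model.

Loads a genome FASTA plus an ORF annotation (GFF3 with CDS features grouped by
parent, or BED12), splices and translates each coding sequence, and extracts
the 10-residue nascent-chain context windows used throughout the stalling
analysis: the eight codons preceding the P-site codon (positions -8..-1), the
P-site codon itself (position 0) and the A-site codon (position +1).

All coordinates are 0-based half-open internally; GFF3's 1-based closed
intervals are converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

logger = logging.getLogger("ribostall")

CONTEXT_POSITIONS: tuple[int, ...] = (-8, -7, -6, -5, -4, -3, -2, -1, 0, 1)
STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = {"ATG"}


def translate_cds(nt_seq: str) -> str:
    """Translate a coding nucleotide sequence with the standard genetic code.

    Stop codons render as ``'*'``; codons containing ambiguous bases render
    as ``'X'`` (logged).  The input length must be a multiple of 3.
    """
    nt_seq = nt_seq.upper().replace("U", "T")
    if len(nt_seq) % 3:
        raise ValueError(f"CDS length {len(nt_seq)} is not a multiple of 3")
    aa = str(Seq(nt_seq).translate())
    if "X" in aa:
        logger.warning(
            "ambiguous bases produced %d 'X' residues in translation", aa.count("X")
        )
    return aa


@dataclass
class OrfRecord:
    """One coding sequence: coordinates plus spliced nucleotide/protein sequence.

    ``cds_intervals`` are genomic 0-based half-open intervals listed in
    transcription order (descending genomic coordinate on the minus strand).
    ``nt_seq`` is the spliced coding sequence on the sense strand (5'->3');
    ``aa_seq`` is the translation including the initiator Met and excluding
    the stop.
    """

    orf_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    nt_seq: str
    aa_seq: str = field(default="")
    check_edges: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be '+' or '-'")
        n = len(self.nt_seq)
        if n % 3 or n < 6:
            raise ValueError(
                f"{self.orf_id}: CDS length {n} must be a multiple of 3 and >= 6"
            )
        span = sum(e - s for s, e in self.cds_intervals)
        if span != n:
            raise ValueError(
                f"{self.orf_id}: interval span {span} != sequence length {n}"
            )
        self._check_intervals()
        if self.check_edges:
            if self.nt_seq[:3].upper() not in START_CODONS:
                raise ValueError(f"{self.orf_id}: does not begin with a start codon")
            if self.nt_seq[-3:].upper() not in STOP_CODONS:
                raise ValueError(f"{self.orf_id}: does not end with a stop codon")
        if not self.aa_seq:
            self.aa_seq = translate_cds(self.nt_seq)[:-1]
        if len(self.aa_seq) != n // 3 - 1:
            raise ValueError(f"{self.orf_id}: aa_seq length mismatch")

    def _check_intervals(self) -> None:
        ivs = self.cds_intervals
        for s, e in ivs:
            if s < 0 or e <= s:
                raise ValueError(f"{self.orf_id}: bad interval ({s}, {e})")
        # transcription order: ascending on +, descending on -; no overlaps
        genomic_sorted = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 < e1:
                raise ValueError(f"{self.orf_id}: overlapping CDS intervals")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if ivs != expected:
            raise ValueError(f"{self.orf_id}: intervals not in transcription order")

    @property
    def n_codons(self) -> int:
        return len(self.nt_seq) // 3

    def __len__(self) -> int:
        return len(self.nt_seq)

    def genomic_to_orf(self, pos: int) -> int | None:
        """ORF-relative nucleotide index of genomic position ``pos``.

        Returns None when the position falls outside every CDS interval.
        """
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        return None

    def orf_to_genomic(self, idx: int) -> int:
        """Genomic coordinate of ORF-relative nucleotide index ``idx``."""
        if not 0 <= idx < len(self.nt_seq):
            raise IndexError(f"{self.orf_id}: nt index {idx} out of range")
        offset = 0
        for s, e in self.cds_intervals:
            w = e - s
            if idx < offset + w:
                within = idx - offset
                return s + within if self.strand == "+" else e - 1 - within
            offset += w
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ContextWindow:
    """Ten residues around a stall: positions -8..-1, 0 (P site), +1 (A site).

    ``'-'`` marks positions truncated by the ORF start (left-anchored run
    only); ``'*'`` marks a stop codon in the A site (position +1 only).
    """

    orf_id: str
    p_codon_index: int
    residues: str
    positions: tuple[int, ...] = CONTEXT_POSITIONS

    def __post_init__(self) -> None:
        r = self.residues
        if len(r) != 10:
            raise ValueError("context must hold exactly 10 symbols")
        if r[8] == "-":
            raise ValueError("P-site residue (position 0) may not be '-'")
        if "*" in r[:9]:
            raise ValueError("'*' allowed only at position +1")
        gap_run = len(r) - len(r.lstrip("-"))
        if "-" in r[gap_run:]:
            raise ValueError("'-' allowed only as a left-anchored run")

    def residue_at(self, position: int) -> str:
        return self.residues[self.positions.index(position)]


def extract_context(orf: OrfRecord, p_codon_index: int) -> ContextWindow:
    """Context window for the ribosome whose P site holds codon ``p_codon_index``.

    Residues are ``aa[p-8..p]`` followed by ``aa[p+1]``; indices before the
    ORF start fill with ``'-'`` and an A-site beyond the last sense codon
    fills with ``'*'`` (stop).
    """
    aa = orf.aa_seq
    if not 0 <= p_codon_index < len(aa):
        raise IndexError(
            f"{orf.orf_id}: P-site codon index {p_codon_index} out of range "
            f"(0..{len(aa) - 1})"
        )
    left = [
        aa[i] if i >= 0 else "-" for i in range(p_codon_index - 8, p_codon_index + 1)
    ]
    a_site = aa[p_codon_index + 1] if p_codon_index + 1 < len(aa) else "*"
    return ContextWindow(orf.orf_id, p_codon_index, "".join(left) + a_site)


# ---------------------------------------------------------------------------
# Annotation loading


def _splice(genome, chrom: str, strand: str, intervals: Sequence[tuple[int, int]]) -> str:
    chunks = []
    for s, e in intervals:
        piece = str(genome[chrom][s:e]).upper()
        if strand == "-":
            piece = str(Seq(piece).reverse_complement())
        chunks.append(piece)
    return "".join(chunks)


def _load_gff3_groups(annotation: str | Path):
    """Yield (orf_id, chrom, strand, genomic-sorted CDS intervals) per ORF.

    CDS features are grouped by their Parent attribute (falling back to ID);
    when one gene carries several transcripts, the first annotated isoform
    (lexicographic) wins and the rest are logged.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    groups: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id or "cds"]
        for parent in parents:
            groups.setdefault(parent, []).append(cds)
    # resolve transcript -> gene so only one isoform per gene survives
    chosen_by_gene: dict[str, str] = {}
    for tid in sorted(groups):
        gene = tid
        try:
            feat = db[tid]
            gene = (feat.attributes.get("Parent") or [tid])[0]
        except gffutils.FeatureNotFoundError:
            pass
        if gene in chosen_by_gene:
            logger.info("skipping isoform %s of gene %s (first isoform wins)", tid, gene)
            continue
        chosen_by_gene[gene] = tid
    for tid in chosen_by_gene.values():
        feats = sorted(groups[tid], key=lambda f: f.start)
        chrom = feats[0].seqid
        strand = feats[0].strand
        intervals = [(f.start - 1, f.end) for f in feats]  # GFF3 1-based closed
        yield tid, chrom, strand, intervals


def _load_bed12_groups(annotation: str | Path):
    with open(annotation) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{annotation}:{line_no}: BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            intervals = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            yield name, chrom, strand, intervals


def load_orfs(
    genome: str | Path,
    annotation: str | Path,
    *,
    strict: bool = False,
    check_edges: bool = True,
) -> list[OrfRecord]:
    """Load ORFs from a genome FASTA and a GFF3 or BED12 annotation.

    Minus-strand sequences are reverse-complemented and multi-exon CDS are
    spliced in transcription order.  ORFs whose length is not a multiple of 3
    are skipped with a warning (``strict=True`` raises instead); a CDS on a
    chromosome absent from the FASTA is always an error.

    Parameters
    ----------
    check_edges:
        Require a start codon at the 5' end and a stop at the 3' end
        (relaxable for synthetic or partial ORFs).
    """
    from pyfaidx import Fasta

    genome_fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    suffix = Path(annotation).suffix.lower()
    groups = (
        _load_bed12_groups(annotation)
        if suffix == ".bed"
        else _load_gff3_groups(annotation)
    )
    orfs: list[OrfRecord] = []
    for orf_id, chrom, strand, intervals in groups:
        if chrom not in genome_fa:
            raise ValueError(f"ORF {orf_id}: chromosome {chrom!r} not in genome FASTA")
        chrom_len = len(genome_fa[chrom])
        for s, e in intervals:
            if e > chrom_len:
                raise ValueError(f"ORF {orf_id}: interval ({s},{e}) beyond {chrom} end")
        tx_order = intervals if strand == "+" else intervals[::-1]
        nt_seq = _splice(genome_fa, chrom, strand, tx_order)
        try:
            orfs.append(
                OrfRecord(orf_id, chrom, strand, tx_order, nt_seq, check_edges=check_edges)
            )
        except ValueError as exc:
            if strict:
                raise
            logger.warning("skipping ORF %s: %s", orf_id, exc)
    return orfs


def orf_table(orfs: Iterable[OrfRecord]):
    """ORF summary as a DataFrame (exportable as TSV)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "orf_id": o.orf_id,
                "chrom": o.chrom,
                "strand": o.strand,
                "length_nt": len(o.nt_seq),
                "aa_seq": o.aa_seq,
            }
            for o in orfs
        ]
    )
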