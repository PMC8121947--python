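"""Footprint alignments to P-site-assigned count tracks.

Each ribosome footprint of acceptable length (25–34 nt by default) is reduced
to a single P-site nucleotide by shifting 18 nt inward from its 3' end, and
contributes one count at that nucleotide within every ORF containing the
position on the matching strand.  Tracks are stored per ORF in ORF-relative
coordinates and normalized to reads-per-million (rpm) against the sample's
total of assigned footprints.

Input is either a coordinate-sorted BAM (primary alignments only) or a pair
of bedGraph files holding 3'-end counts — the paired-file dialect is one file
per strand (plus, minus), values at the genomic position of the footprint
3'-end nucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .annotation import OrfRecord
from .config import DEFAULT_CONFIG, PipelineConfig

logger = logging.getLogger("ribostall")


def filter_by_length(read_length: int, min_len: int = 25, max_len: int = 34) -> bool:
    """True iff the footprint length is inside the inclusive window."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    return min_len <= read_length <= max_len


def assign_psite(three_prime_pos: int, strand: str, offset: int = 18) -> int | None:
    """P-site genomic coordinate from a footprint 3'-end coordinate.

    Plus-strand footprints shift upstream (−offset), minus-strand downstream
    (+offset).  Returns None (read discarded) when the shift underflows the
    chromosome start.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    pos = three_prime_pos - offset if strand == "+" else three_prime_pos + offset
    if pos < 0:
        logger.debug("P-site underflow at %d (%s); read discarded", three_prime_pos, strand)
        return None
    return pos


@dataclass
class SampleTrack:
    """Per-ORF P-site count vectors for one sample.

    ``total_mapped`` counts each retained footprint once even when it falls
    in several overlapping ORFs (each containing ORF is still incremented).
    """

    sample_id: str
    condition: str
    replicate: int
    counts: dict[str, np.ndarray]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.condition not in ("treated", "control"):
            raise ValueError("condition must be 'treated' or 'control'")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def __add__(self, other: "SampleTrack") -> "SampleTrack":
        if set(self.counts) != set(other.counts):
            raise ValueError("tracks cover different ORF sets")
        return SampleTrack(
            self.sample_id,
            self.condition,
            self.replicate,
            {k: self.counts[k] + other.counts[k] for k in self.counts},
            self.total_mapped + other.total_mapped,
        )


@dataclass
class RpmTrack:
    """Reads-per-million view of a :class:`SampleTrack`."""

    sample_id: str
    condition: str
    replicate: int
    rpm: dict[str, np.ndarray]
    total_mapped: int


def normalize_rpm(track: SampleTrack) -> RpmTrack:
    """rpm[i] = counts[i] / total_mapped * 1e6."""
    if track.total_mapped <= 0:
        raise ValueError(f"no mapped footprints in sample {track.sample_id}")
    scale = 1e6 / track.total_mapped
    return RpmTrack(
        track.sample_id,
        track.condition,
        track.replicate,
        {orf: c.astype(float) * scale for orf, c in track.counts.items()},
        track.total_mapped,
    )


# ---------------------------------------------------------------------------
# Track building


class _OrfIndex:
    """Interval index: (chrom, strand, genomic pos) -> containing ORFs."""

    def __init__(self, orfs: Sequence[OrfRecord]):
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for orf in orfs:
            tree = self.trees.setdefault((orf.chrom, orf.strand), IntervalTree())
            for s, e in orf.cds_intervals:
                tree.addi(s, e, orf)

    def lookup(self, chrom: str, strand: str, pos: int) -> list[OrfRecord]:
        tree = self.trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def _iter_bam_ends(path: str | Path, min_len: int, max_len: int):
    """Yield (chrom, strand, 3'-end position, 1) per retained primary alignment."""
    import pysam

    # mode auto-detected so plain-text SAM works alongside BAM
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not filter_by_length(read.query_alignment_length, min_len, max_len):
                continue
            # soft clips excluded: use aligned reference ends
            if read.is_reverse:
                yield read.reference_name, "-", read.reference_start, 1
            else:
                yield read.reference_name, "+", read.reference_end - 1, 1


def _iter_bedgraph_ends(plus: str | Path | None, minus: str | Path | None):
    """Yield (chrom, strand, 3'-end position, count) from paired bedGraphs."""
    for path, strand in ((plus, "+"), (minus, "-")):
        if path is None:
            continue
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                count = int(round(float(value)))
                for pos in range(int(start), int(end)):
                    yield chrom, strand, pos, count


def build_track(
    alignments: str | Path | tuple,
    orfs: Sequence[OrfRecord],
    condition: str,
    replicate: int,
    *,
    sample_id: str | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SampleTrack:
    """Build a P-site count track from a BAM or a (plus, minus) bedGraph pair.

    Footprints are length-filtered (BAM path only; bedGraph tracks are taken
    as already length-selected 3'-end counts), shifted ``config.psite_offset``
    nt inward from the 3' end, and counted into every ORF containing the
    resulting position on the matching strand.  With ``config.unique_orf``
    reads landing in more than one ORF are dropped instead.
    """
    index = _OrfIndex(orfs)
    counts = {o.orf_id: np.zeros(len(o.nt_seq), dtype=np.int64) for o in orfs}
    if isinstance(alignments, (tuple, list)):
        source = _iter_bedgraph_ends(*alignments)
    else:
        source = _iter_bam_ends(alignments, config.min_len, config.max_len)

    total_mapped = 0
    known_chroms = {c for c, _ in index.trees}
    seen_unmatched: set[str] = set()
    for chrom, strand, end_pos, n in source:
        if chrom not in known_chroms:
            seen_unmatched.add(chrom)
            continue
        pos = assign_psite(end_pos, strand, config.psite_offset)
        if pos is None:
            continue
        hits = index.lookup(chrom, strand, pos)
        if not hits or (config.unique_orf and len(hits) > 1):
            continue
        for orf in hits:
            idx = orf.genomic_to_orf(pos)
            if idx is not None:
                counts[orf.orf_id][idx] += n
        total_mapped += n
    if seen_unmatched:
        if total_mapped == 0:
            raise ValueError(
                f"no contig names matched the annotation: {sorted(seen_unmatched)}"
            )
        logger.warning("ignored alignments on unannotated contigs: %s", sorted(seen_unmatched))
    sid = sample_id or f"{condition}_rep{replicate}"
    return SampleTrack(sid, condition, replicate, counts, total_mapped)


def write_bedgraph(track: SampleTrack, orfs: Sequence[OrfRecord], plus_path, minus_path) -> None:
    """Export P-site counts as a (plus, minus) bedGraph pair for inspection."""
    orf_by_id = {o.orf_id: o for o in orfs}
    handles = {"+": open(plus_path, "w"), "-": open(minus_path, "w")}
    try:
        per_strand: dict[str, dict[tuple[str, int], int]] = {"+": {}, "-": {}}
        for orf_id, vec in track.counts.items():
            orf = orf_by_id[orf_id]
            for idx in np.nonzero(vec)[0]:
                g = orf.orf_to_genomic(int(idx))
                key = (orf.chrom, g)
                per_strand[orf.strand][key] = per_strand[orf.strand].get(key, 0) + int(vec[idx])
        for strand, data in per_strand.items():
            for (chrom, pos), val in sorted(data.items()):
                handles[strand].write(f"{chrom}\t{pos}\t{pos + 1}\t{val}\n")
    finally:
        for h in handles.values():
            h.close()
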