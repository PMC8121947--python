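"""Synthetic genomes and footprint tracks with planted arrest sites.

The generator emulates the structure of a two-condition ribosome-profiling
experiment: random-codon ORFs of realistic lengths, per-gene expression
spanning ~3 orders of magnitude, overdispersed (negative-binomial) codon
counts, independent replicate sampling noise, and arrest sites of known
motif class whose P-site codon mean is multiplied in the treated condition
only.  A truth table records every planted site so selection sensitivity and
false discovery proportion can be measured end to end.

All randomness flows from a single seed through numpy SeedSequence spawning,
so identical specs give byte-identical genomes and tracks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import OrfRecord, extract_context
from .logo import classify_context
from .tracks import SampleTrack

logger = logging.getLogger("ribostall")

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_K_CODONS = ["AAA", "AAG"]
_R_CODONS = ["AGA", "AGG", "CGT", "CGC", "CGA", "CGG"]
_P_CODONS = ["CCA", "CCT", "CCC", "CCG"]
_D_CODONS = ["GAT", "GAC"]
_POSITIVE_CODONS = _K_CODONS + _R_CODONS


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic experiment.

    Defaults give a compact two-replicate experiment: 60 genes of 120–400
    codons, per-gene mean footprint counts per codon log-uniform over
    0.6–600 (~3 orders of magnitude of expression), negative-binomial
    dispersion 10, and 30 planted arrest sites with an 8-fold treated-only
    pause.  ``dispersion=None`` gives the Poisson limit.
    """

    n_genes: int = 60
    length_range_codons: tuple[int, int] = (120, 400)
    mean_count_range: tuple[float, float] = (0.6, 600.0)
    dispersion: float | None = 10.0
    planted: list[tuple[str, float]] = field(
        default_factory=lambda: [("+X+", 8.0)] * 15 + [("PDX", 8.0)] * 10 + [("PXX", 8.0)] * 5
    )
    replicates: int = 2
    depth_factor: float = 1.0
    intron_fraction: float = 0.2
    minus_strand_fraction: float = 0.3
    flank: int = 100
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")
        for cls, m in self.planted:
            if m < 1:
                raise ValueError(f"planted multiplier {m} must be >= 1")
            if cls not in ("+X+", "PDX", "PXX"):
                raise ValueError(f"unknown planted class {cls!r}")
        if self.length_range_codons[0] < 40:
            raise ValueError("genes must be at least 40 codons for full windows")


@dataclass
class SyntheticGenome:
    """Chromosome sequences, ORF records and the planted-site truth table."""

    chromosomes: dict[str, str]
    orfs: list[OrfRecord]
    truth: pd.DataFrame  # orf_id, codon_index, motif_class, multiplier
    gene_means: dict[str, float]


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = ["ATG"]
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    codons += [_SENSE_CODONS[i] for i in idx]
    codons.append("TAA")
    return codons


def _plant_motif(rng: np.random.Generator, codons: list[str], p: int, cls: str) -> None:
    """Overwrite codons so the translated context at P-site codon p has class cls."""
    if cls == "+X+":
        codons[p - 1] = _POSITIVE_CODONS[rng.integers(len(_POSITIVE_CODONS))]
        codons[p + 1] = _POSITIVE_CODONS[rng.integers(len(_POSITIVE_CODONS))]
    elif cls == "PDX":
        codons[p - 1] = _P_CODONS[rng.integers(len(_P_CODONS))]
        codons[p] = _D_CODONS[rng.integers(len(_D_CODONS))]
    else:  # PXX: Pro at -1, P site neither D nor flanked K/R pair
        codons[p - 1] = _P_CODONS[rng.integers(len(_P_CODONS))]
        while codons[p] in _D_CODONS:
            codons[p] = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def make_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Generate chromosomes, ORFs and the truth table for one experiment.

    One gene per chromosome with random flanks; a fraction of genes sit on
    the minus strand and a fraction carry one intron, so the synthetic path
    exercises strand handling and splicing in the same readers as real data.
    Planted sites are placed >= 17 codons from either ORF end (full context
    window and full metagene window) and re-drawn on collision.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.random_seed).spawn(1)[0])
    lo, hi = spec.length_range_codons
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    gene_codons = [_random_cds(rng, int(n)) for n in lengths]
    gene_ids = [f"gene{i:04d}" for i in range(spec.n_genes)]

    # assign planted sites to genes (round-robin over shuffled genes so the
    # number of planted sites may exceed n_genes)
    order = rng.permutation(spec.n_genes)
    truth_rows = []
    occupied: dict[int, list[int]] = {}
    for site_i, (cls, mult) in enumerate(spec.planted):
        g = int(order[site_i % spec.n_genes])
        codons = gene_codons[g]
        n_codons = len(codons)
        for _ in range(200):
            p = int(rng.integers(17, n_codons - 18))
            if all(abs(p - q) > 4 for q in occupied.get(g, [])):
                break
        else:
            logger.warning("could not place planted site %d in %s; skipped", site_i, gene_ids[g])
            continue
        occupied.setdefault(g, []).append(p)
        _plant_motif(rng, codons, p, cls)
        truth_rows.append(
            {"orf_id": gene_ids[g], "codon_index": p, "motif_class": cls, "multiplier": mult}
        )

    chromosomes: dict[str, str] = {}
    orfs: list[OrfRecord] = []
    for g, (gid, codons) in enumerate(zip(gene_ids, gene_codons)):
        cds = "".join(codons)
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        has_intron = rng.random() < spec.intron_fraction and len(cds) > 60
        chrom = f"chr{g:04d}"
        flank5 = "".join(rng.choice(list("ACGT"), size=spec.flank))
        flank3 = "".join(rng.choice(list("ACGT"), size=spec.flank))
        if has_intron:
            cut = int(rng.integers(30, len(cds) - 30))
            intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 80))))
            tx_pieces = [cds[:cut], cds[cut:]]
        else:
            intron = ""
            tx_pieces = [cds]
        # genomic layout in transcription order, then flip for minus strand
        sense = flank5 + tx_pieces[0] + intron + (tx_pieces[1] if intron else "") + flank3
        s0 = spec.flank
        if intron:
            iv_tx = [
                (s0, s0 + len(tx_pieces[0])),
                (s0 + len(tx_pieces[0]) + len(intron), s0 + len(tx_pieces[0]) + len(intron) + len(tx_pieces[1])),
            ]
        else:
            iv_tx = [(s0, s0 + len(cds))]
        if strand == "+":
            chromosomes[chrom] = sense
            intervals = iv_tx
        else:
            chromosomes[chrom] = _revcomp(sense)
            L = len(sense)
            intervals = [(L - e, L - s) for s, e in iv_tx]  # still transcription order
        orfs.append(OrfRecord(gid, chrom, strand, intervals, cds))

    truth = pd.DataFrame(truth_rows, columns=["orf_id", "codon_index", "motif_class", "multiplier"])
    # verify planted contexts genuinely carry their motif class
    orf_by_id = {o.orf_id: o for o in orfs}
    for row in truth.itertuples(index=False):
        got = classify_context(extract_context(orf_by_id[row.orf_id], row.codon_index))
        assert got == row.motif_class, (row, got)

    mu_lo, mu_hi = spec.mean_count_range
    means = np.exp(rng.uniform(math.log(mu_lo), math.log(mu_hi), size=spec.n_genes))
    gene_means = dict(zip(gene_ids, means.astype(float)))
    return SyntheticGenome(chromosomes, orfs, truth, gene_means)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float | None) -> np.ndarray:
    if phi is None or math.isinf(phi):
        return rng.poisson(mu)
    p = phi / (phi + mu)
    return rng.negative_binomial(phi, p)


def simulate_tracks(spec: SyntheticSpec, genome: SyntheticGenome) -> dict[str, SampleTrack]:
    """Simulate one SampleTrack per condition x replicate.

    Codon counts are NB(mu_gene x depth, phi), independently per sample;
    planted codons' means are multiplied in treated samples only; each codon
    count is split uniformly at random over its 3 nucleotides.
    """
    if spec.depth_factor <= 0:
        raise ValueError("depth_factor must be positive")
    planted_by_orf: dict[str, list[tuple[int, float]]] = {}
    for row in genome.truth.itertuples(index=False):
        planted_by_orf.setdefault(row.orf_id, []).append((row.codon_index, row.multiplier))

    seeds = np.random.SeedSequence(spec.random_seed).spawn(2 * spec.replicates + 1)[1:]
    tracks: dict[str, SampleTrack] = {}
    sample_i = 0
    for condition in ("control", "treated"):
        for rep in range(1, spec.replicates + 1):
            rng = np.random.default_rng(seeds[sample_i])
            sample_i += 1
            counts: dict[str, np.ndarray] = {}
            total = 0
            for orf in genome.orfs:
                n_codons = orf.n_codons
                mu = np.full(n_codons, genome.gene_means[orf.orf_id] * spec.depth_factor)
                if condition == "treated":
                    for p, m in planted_by_orf.get(orf.orf_id, []):
                        mu[p] *= m
                codon_counts = _draw_counts(rng, mu, spec.dispersion)
                nt = np.zeros(3 * n_codons, dtype=np.int64)
                nz = np.nonzero(codon_counts)[0]
                if len(nz):
                    split = rng.multinomial(codon_counts[nz], [1 / 3, 1 / 3, 1 / 3])
                    for row_i, j in enumerate(nz):
                        nt[3 * j : 3 * j + 3] = split[row_i]
                counts[orf.orf_id] = nt
                total += int(nt.sum())
            if total == 0:
                raise ValueError("simulated sample has zero footprints; raise depth")
            sid = f"{condition}_rep{rep}"
            tracks[sid] = SampleTrack(sid, condition, rep, counts, total)
    return tracks


def evaluate_recovery(
    selected,
    truth: pd.DataFrame,
    *,
    tolerance_codons: int = 1,
) -> dict[str, float]:
    """Sensitivity and false discovery proportion of site selection.

    A planted site counts as recovered when a selected site lies within
    ``tolerance_codons`` of it in the same ORF (nucleotide-level count
    splitting can shift the peak codon by one); a selected site matching no
    planted site within the tolerance counts toward the FDP.  Exact-codon
    sensitivity is reported alongside.
    """
    if truth.empty:
        raise ValueError("truth table is empty; nothing to recover")
    planted = [(r.orf_id, r.codon_index) for r in truth.itertuples(index=False)]
    sel = [(s.orf_id, s.codon_index) for s in selected]
    sel_set = set(sel)

    def near(a, b):
        return a[0] == b[0] and abs(a[1] - b[1]) <= tolerance_codons

    recovered = sum(1 for p in planted if any(near(p, s) for s in sel_set))
    recovered_exact = sum(1 for p in planted if p in sel_set)
    false_pos = sum(1 for s in sel_set if not any(near(s, p) for p in planted))
    return {
        "sensitivity": recovered / len(planted),
        "sensitivity_exact": recovered_exact / len(planted),
        "fdp": false_pos / len(sel_set) if sel_set else 0.0,
        "n_planted": float(len(planted)),
        "n_selected": float(len(sel_set)),
    }


# ---------------------------------------------------------------------------
# File emission (FASTA / GFF3 / bedGraph / truth TSV)


def write_genome_files(genome: SyntheticGenome, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.gff3 and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(genome.chromosomes):
            fh.write(f">{chrom}\n")
            seq = genome.chromosomes[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    gff = outdir / "annotation.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in genome.orfs:
            g_start = min(s for s, _ in orf.cds_intervals) + 1
            g_end = max(e for _, e in orf.cds_intervals)
            fh.write(
                f"{orf.chrom}\tribostall\tgene\t{g_start}\t{g_end}\t.\t{orf.strand}\t.\t"
                f"ID={orf.orf_id}_g\n"
            )
            fh.write(
                f"{orf.chrom}\tribostall\tmRNA\t{g_start}\t{g_end}\t.\t{orf.strand}\t.\t"
                f"ID={orf.orf_id};Parent={orf.orf_id}_g\n"
            )
            phase = 0
            for s, e in orf.cds_intervals:
                fh.write(
                    f"{orf.chrom}\tribostall\tCDS\t{s + 1}\t{e}\t.\t{orf.strand}\t{phase}\t"
                    f"ID=cds_{orf.orf_id};Parent={orf.orf_id}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3
    truth_path = outdir / "truth.tsv"
    genome.truth.to_csv(truth_path, sep="\t", index=False)
    return {"fasta": fasta, "gff3": gff, "truth": truth_path}


def write_track_bedgraphs(
    track: SampleTrack,
    genome: SyntheticGenome,
    outdir: str | Path,
    psite_offset: int = 18,
) -> tuple[Path, Path]:
    """Write a (plus, minus) 3'-end count bedGraph pair for one sample.

    Counts are placed at the genomic 3'-end position that the track-building
    P-site shift maps back onto the simulated P-site nucleotide, so reading
    the pair with the standard offset reproduces the track exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    orf_by_id = {o.orf_id: o for o in genome.orfs}
    per_strand: dict[str, dict[tuple[str, int], int]] = {"+": {}, "-": {}}
    for orf_id, vec in track.counts.items():
        orf = orf_by_id[orf_id]
        for idx in np.nonzero(vec)[0]:
            g = orf.orf_to_genomic(int(idx))
            end = g + psite_offset if orf.strand == "+" else g - psite_offset
            key = (orf.chrom, end)
            per_strand[orf.strand][key] = per_strand[orf.strand].get(key, 0) + int(vec[idx])
    plus = outdir / f"{track.sample_id}.plus.bedgraph"
    minus = outdir / f"{track.sample_id}.minus.bedgraph"
    for path, strand in ((plus, "+"), (minus, "-")):
        with open(path, "w") as fh:
            for (chrom, pos), val in sorted(per_strand[strand].items()):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{val}\n")
    return plus, minus
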