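"""Gene scores, pause scores and treated/control pause ratios.

The pause score of a nucleotide is its rpm divided by the mean rpm over the
whole gene, so a score of 1 is the gene average and the per-gene mean of
nucleotide pause scores is exactly 1.  Codon pause scores average the three
nucleotide scores of the codon.  Drug-induced pausing is quantified as the
ratio of treated to control codon pause scores, computed per replicate pair
and restricted to codons passing the signal-inclusion rule in both samples.

Gene scores are rpkm: rpm summed over the ORF divided by ORF length in
kilobases; genes below the active-expression cutoff in any sample are
excluded from ratio analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import OrfRecord
from .config import DEFAULT_CONFIG, PipelineConfig
from .tracks import RpmTrack

logger = logging.getLogger("ribostall")


@dataclass
class GeneScore:
    orf_id: str
    rpkm: float
    active: bool


@dataclass
class PauseProfile:
    """Per-nucleotide and per-codon pause scores for one ORF in one sample.

    ``included`` flags nucleotides passing the inclusion rule for ratio
    computation; all nucleotides contribute to the gene mean regardless.
    """

    orf_id: str
    sample_id: str
    nt_scores: np.ndarray
    codon_scores: np.ndarray
    included: np.ndarray  # bool per nucleotide


def gene_scores(
    rpm_track: RpmTrack,
    orfs: list[OrfRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[GeneScore]:
    """rpkm (gene score) per ORF; genes under ``min_gene_rpkm`` flagged inactive."""
    out = []
    for orf in orfs:
        rpm = rpm_track.rpm[orf.orf_id]
        rpkm = float(rpm.sum()) / (len(orf.nt_seq) / 1000.0)
        out.append(GeneScore(orf.orf_id, rpkm, rpkm >= config.min_gene_rpkm))
    return out


def pause_scores(
    rpm_track: RpmTrack,
    orf: OrfRecord,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PauseProfile | None:
    """Pause profile of one ORF in one sample; None when the ORF has no signal."""
    rpm = rpm_track.rpm[orf.orf_id]
    mean = rpm.mean()
    if mean == 0:
        logger.debug("ORF %s has zero rpm in %s; no profile", orf.orf_id, rpm_track.sample_id)
        return None
    nt = rpm / mean
    codon = nt.reshape(-1, 3).mean(axis=1)
    if config.inclusion_units == "rpm":
        included = rpm >= config.inclusion_threshold
    else:
        included = nt >= config.inclusion_threshold
    return PauseProfile(orf.orf_id, rpm_track.sample_id, nt, codon, included)


def pause_ratios(
    treated: PauseProfile,
    control: PauseProfile,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[int, float]:
    """Treated/control codon pause-score ratios for one ORF and replicate pair.

    A nucleotide enters ratio computation only when it passes the inclusion
    rule in BOTH samples; a codon is included when at least one of its three
    nucleotides is included and its control codon score is positive.  Returns
    {codon_index: ratio} for the included codons only.
    """
    if treated.orf_id != control.orf_id:
        raise ValueError("profiles are for different ORFs")
    both = treated.included & control.included
    codon_ok = both.reshape(-1, 3).any(axis=1)
    n_codons = len(codon_ok)
    # the stop codon holds no P-site amino acid and is never a site
    lo = config.trim_codons
    hi = min(n_codons - 1, n_codons - config.trim_codons)
    out: dict[int, float] = {}
    for j in np.nonzero(codon_ok)[0]:
        if not lo <= j < hi:
            continue
        c = control.codon_scores[j]
        if c > 0:
            out[int(j)] = float(treated.codon_scores[j] / c)
    return out


def build_ratio_table(
    rpm_tracks: dict[str, RpmTrack],
    orfs: list[OrfRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Pause-ratio table over all active ORFs and replicate pairs.

    Replicate pairing is treated rep i vs control rep i.  A (orf, codon) row
    appears only when the ratio is defined in every replicate pair, so the
    table is a single shared universe for site selection and the logo
    background.  Columns: orf_id, codon_index, ratio_rep<i>...
    """
    treated = sorted(
        (t for t in rpm_tracks.values() if t.condition == "treated"),
        key=lambda t: t.replicate,
    )
    control = sorted(
        (t for t in rpm_tracks.values() if t.condition == "control"),
        key=lambda t: t.replicate,
    )
    if not treated or not control:
        raise ValueError("need at least one treated and one control sample")
    if len(treated) != len(control):
        raise ValueError("unpaired replicates between conditions")
    if len(treated) < 2:
        logger.warning("fewer than 2 replicate pairs; selection is single-replicate")

    # active genes: rpkm cutoff in every sample
    active = None
    for track in list(treated) + list(control):
        ids = {g.orf_id for g in gene_scores(track, orfs, config) if g.active}
        active = ids if active is None else active & ids
    orfs_active = [o for o in orfs if o.orf_id in (active or set())]
    n_dropped = len(orfs) - len(orfs_active)
    if n_dropped:
        logger.info("dropped %d ORFs below min_gene_rpkm=%s", n_dropped, config.min_gene_rpkm)

    rows = []
    for orf in orfs_active:
        per_pair: list[dict[int, float]] = []
        ok = True
        for t_track, c_track in zip(treated, control):
            tp = pause_scores(t_track, orf, config)
            cp = pause_scores(c_track, orf, config)
            if tp is None or cp is None:
                ok = False
                break
            per_pair.append(pause_ratios(tp, cp, config))
        if not ok or not per_pair:
            continue
        shared = set(per_pair[0])
        for d in per_pair[1:]:
            shared &= set(d)
        for j in sorted(shared):
            row = {"orf_id": orf.orf_id, "codon_index": j}
            for i, d in enumerate(per_pair, 1):
                row[f"ratio_rep{i}"] = d[j]
            rows.append(row)
    cols = ["orf_id", "codon_index"] + [f"ratio_rep{i}" for i in range(1, len(treated) + 1)]
    table = pd.DataFrame(rows, columns=cols)
    logger.info("pause-ratio universe: %d codon sites", len(table))
    return table


def gene_score_table(
    rpm_tracks: dict[str, RpmTrack],
    orfs: list[OrfRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """rpkm per ORF per sample, wide format."""
    data: dict[str, dict[str, float]] = {}
    for sid, track in sorted(rpm_tracks.items()):
        for g in gene_scores(track, orfs, config):
            data.setdefault(g.orf_id, {})[f"rpkm_{sid}"] = g.rpkm
    df = pd.DataFrame.from_dict(data, orient="index").rename_axis("orf_id").reset_index()
    return df
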