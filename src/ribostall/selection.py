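"""Selection of drug-arrest and least-sensitive codon sites.

Strong arrest sites show a >= strong_fold (default 2.5) increase of the codon
pause score under treatment in EVERY replicate pair; least-sensitive ("weak")
sites show a >= weak_fold (default 2) decrease in every pair.  Each selected
site carries its 10-residue nascent-chain context; the background universe
for enrichment analysis is the context of every codon in the ratio table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotation import ContextWindow, OrfRecord, extract_context
from .config import DEFAULT_CONFIG, PipelineConfig

logger = logging.getLogger("ribostall")


@dataclass
class StallSite:
    orf_id: str
    codon_index: int
    ratios: tuple[float, ...]
    context: ContextWindow
    direction: str  # "strong" | "weak"
    motif_class: str = "other"


def _ratio_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("ratio_rep")]
    if not cols:
        raise ValueError("ratio table has no ratio_rep columns")
    return cols


def _contexts_ok(config: PipelineConfig, codon_index: int) -> bool:
    return not (config.exclude_orf_start_windows and codon_index < 9)


def select_strong_sites(
    table: pd.DataFrame,
    orfs: list[OrfRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    allow_single_replicate: bool = False,
) -> list[StallSite]:
    """Sites with ratio >= strong_fold in every replicate pair (inclusive)."""
    cols = _ratio_columns(table)
    if len(cols) < 2 and not allow_single_replicate:
        logger.warning("fewer than 2 replicate ratio columns; pass allow_single_replicate=True")
        raise ValueError("strong-site selection requires >= 2 replicate pairs")
    orf_by_id = {o.orf_id: o for o in orfs}
    mask = (table[cols] >= config.strong_fold).all(axis=1)
    sites = []
    for row in table[mask].itertuples(index=False):
        if not _contexts_ok(config, row.codon_index):
            continue
        ctx = extract_context(orf_by_id[row.orf_id], row.codon_index)
        ratios = tuple(getattr(row, c) for c in cols)
        sites.append(StallSite(row.orf_id, row.codon_index, ratios, ctx, "strong"))
    logger.info("selected %d strong arrest sites (fold >= %s)", len(sites), config.strong_fold)
    return sites


def select_weak_sites(
    table: pd.DataFrame,
    orfs: list[OrfRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    allow_single_replicate: bool = False,
) -> list[StallSite]:
    """Sites with ratio <= 1/weak_fold in every replicate pair.

    With ``config.weak_all_replicates=False`` a single qualifying pair
    suffices.
    """
    cols = _ratio_columns(table)
    if len(cols) < 2 and not allow_single_replicate:
        raise ValueError("weak-site selection requires >= 2 replicate pairs")
    orf_by_id = {o.orf_id: o for o in orfs}
    cutoff = 1.0 / config.weak_fold
    hits = table[cols] <= cutoff
    mask = hits.all(axis=1) if config.weak_all_replicates else hits.any(axis=1)
    sites = []
    for row in table[mask].itertuples(index=False):
        if not _contexts_ok(config, row.codon_index):
            continue
        ctx = extract_context(orf_by_id[row.orf_id], row.codon_index)
        ratios = tuple(getattr(row, c) for c in cols)
        sites.append(StallSite(row.orf_id, row.codon_index, ratios, ctx, "weak"))
    logger.info("selected %d least-sensitive sites (fold <= 1/%s)", len(sites), config.weak_fold)
    return sites


def background_universe(
    table: pd.DataFrame,
    orfs: list[OrfRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ContextWindow]:
    """One context per codon in the ratio table (the logo background)."""
    orf_by_id = {o.orf_id: o for o in orfs}
    out = []
    for row in table.itertuples(index=False):
        if not _contexts_ok(config, row.codon_index):
            continue
        out.append(extract_context(orf_by_id[row.orf_id], row.codon_index))
    return out


def sites_table(sites: list[StallSite]) -> pd.DataFrame:
    """Stall sites as a DataFrame (stall_sites.tsv layout)."""
    rows = []
    for s in sites:
        row = {"orf_id": s.orf_id, "codon_index": s.codon_index}
        for i, r in enumerate(s.ratios, 1):
            row[f"ratio_rep{i}"] = r
        row["context"] = s.context.residues
        row["motif_class"] = s.motif_class
        row["direction"] = s.direction
        rows.append(row)
    return pd.DataFrame(rows)
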