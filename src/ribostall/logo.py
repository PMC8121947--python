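"""Positional residue enrichment logos and arrest-motif classification.

The enrichment statistic is the signed binomial tail log-odds used by
sequence-logo significance tools: for a residue observed k times among n
foreground contexts at a position, with background frequency p,

    score = -log10 P[X >= k]   if k/n >= p   (enrichment, positive)
    score = +log10 P[X <= k]   otherwise     (depletion, negative)

with X ~ Binomial(n, p) and exact tail probabilities.  Cells are significant
when |score| exceeds the Bonferroni-corrected threshold
-log10(alpha / (20 residues x 10 positions)).

Arrest motifs are classified from the nascent-chain context: "+X+" has
Arg/Lys at both -1 (penultimate residue) and +1 (A site); "PDX" has Pro at
-1 with Asp in the P site; "PXX" is the remaining Pro-at--1 class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .annotation import CONTEXT_POSITIONS, ContextWindow

logger = logging.getLogger("ribostall")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
POSITIVE = frozenset("KR")
MOTIF_CLASSES = ("+X+", "PDX", "PXX", "other")

_LN10 = math.log(10.0)


def binomial_logo_score(k: int, n: int, p: float) -> float:
    """Signed -log10 binomial tail probability of k successes in n at rate p."""
    if not 0 < p < 1:
        raise ValueError(f"background frequency p={p} must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return 0.0
    if k / n >= p:
        return -binom.logsf(k - 1, n, p) / _LN10  # P[X >= k]
    return binom.logcdf(k, n, p) / _LN10  # P[X <= k], sign negative


@dataclass
class LogoMatrix:
    """Long-format positions x residues table of counts and log-odds scores.

    ``table`` columns: position, residue, k (foreground count), n (foreground
    total at that position, gaps/stops excluded), p (background frequency),
    score, significant.
    """

    table: pd.DataFrame
    alpha: float
    threshold: float

    def cell(self, position: int, residue: str) -> pd.Series:
        t = self.table
        hit = t[(t.position == position) & (t.residue == residue)]
        if hit.empty:
            raise KeyError((position, residue))
        return hit.iloc[0]

    def top_residues(self, position: int, k: int = 1) -> list[str]:
        """Residues with the k highest enrichment scores at a position."""
        t = self.table[self.table.position == position].dropna(subset=["score"])
        return list(t.sort_values("score", ascending=False).residue.head(k))

    def significant_cells(self) -> pd.DataFrame:
        return self.table[self.table.significant]


def _position_counts(contexts: list[ContextWindow]) -> pd.DataFrame:
    """Residue counts per window position; '-' and '*' symbols excluded."""
    counts = np.zeros((len(CONTEXT_POSITIONS), len(AMINO_ACIDS)), dtype=np.int64)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for ctx in contexts:
        for pos_i, res in enumerate(ctx.residues):
            j = aa_index.get(res)
            if j is not None:
                counts[pos_i, j] += 1
    return pd.DataFrame(counts, index=list(CONTEXT_POSITIONS), columns=list(AMINO_ACIDS))


def build_logo(
    foreground: list[ContextWindow],
    background: list[ContextWindow],
    alpha: float = 0.05,
    *,
    position_specific: bool = True,
) -> LogoMatrix:
    """Enrichment logo of foreground contexts against a background set.

    Background frequencies are computed per position by default (pooled over
    positions with ``position_specific=False``).  Cells whose background
    frequency is 0 or 1 have no defined binomial score and carry NaN.
    """
    if not foreground:
        raise ValueError("empty foreground context set")
    if not background:
        raise ValueError("empty background context set")
    fg = _position_counts(foreground)
    bg = _position_counts(background)
    if position_specific:
        bg_freq = bg.div(bg.sum(axis=1), axis=0)
    else:
        pooled = bg.sum(axis=0) / bg.values.sum()
        bg_freq = pd.DataFrame(
            np.tile(pooled.values, (len(CONTEXT_POSITIONS), 1)),
            index=bg.index,
            columns=bg.columns,
        )
    threshold = -math.log10(alpha / (len(AMINO_ACIDS) * len(CONTEXT_POSITIONS)))
    rows = []
    for pos in CONTEXT_POSITIONS:
        n = int(fg.loc[pos].sum())
        for res in AMINO_ACIDS:
            k = int(fg.loc[pos, res])
            p = float(bg_freq.loc[pos, res])
            if 0 < p < 1 and n > 0:
                score = binomial_logo_score(k, n, p)
            else:
                score = float("nan")
            rows.append(
                {
                    "position": pos,
                    "residue": res,
                    "k": k,
                    "n": n,
                    "p": p,
                    "score": score,
                    "significant": bool(not math.isnan(score) and abs(score) > threshold),
                }
            )
    return LogoMatrix(pd.DataFrame(rows), alpha, threshold)


def condition_on(
    contexts: list[ContextWindow],
    position: int,
    residue_set: str | frozenset | set,
) -> list[ContextWindow]:
    """Contexts whose residue at ``position`` lies in ``residue_set``.

    Reproduces the fixed-residue conditioning used to isolate motif
    subclasses (e.g. fix -1 and +1 to {K, R} for +X+; fix -1 to P for PXX).
    """
    if position not in CONTEXT_POSITIONS:
        raise ValueError(f"position {position} not in {CONTEXT_POSITIONS}")
    wanted = set(residue_set)
    subset = [c for c in contexts if c.residue_at(position) in wanted]
    if not subset:
        raise ValueError(
            f"conditioning on {sorted(wanted)} at position {position} leaves 0 of "
            f"{len(contexts)} contexts"
        )
    return subset


def classify_context(context: ContextWindow) -> str:
    """Motif class of a stall context: '+X+', 'PDX', 'PXX' or 'other'.

    Priority +X+ > PDX > PXX (the rules cannot co-fire since Pro is not a
    positively charged residue, but the order is fixed regardless).
    """
    minus1 = context.residue_at(-1)
    p_site = context.residue_at(0)
    a_site = context.residue_at(1)
    if minus1 in POSITIVE and a_site in POSITIVE:
        return "+X+"
    if minus1 == "P" and p_site == "D":
        return "PDX"
    if minus1 == "P":
        return "PXX"
    return "other"


def scan_protein_motifs(aa_seq: str) -> list[tuple[int, str]]:
    """Predicted arrest positions within a protein sequence.

    Returns (P-site codon index, class) for every +X+ and PDX occurrence;
    overlapping/tandem motifs are all reported.
    """
    if len(aa_seq) < 3:
        raise ValueError("protein must be at least 3 residues long")
    hits = []
    for i in range(1, len(aa_seq)):
        if i + 1 < len(aa_seq) and aa_seq[i - 1] in POSITIVE and aa_seq[i + 1] in POSITIVE:
            hits.append((i, "+X+"))
        elif aa_seq[i - 1] == "P" and aa_seq[i] == "D":
            hits.append((i, "PDX"))
    return hits


def class_summary(classes: list[str]) -> pd.DataFrame:
    """Counts and percentages per motif class (pie-chart numbers)."""
    total = len(classes)
    rows = []
    for cls in MOTIF_CLASSES:
        n = classes.count(cls)
        rows.append({"motif_class": cls, "count": n, "percent": 100.0 * n / total if total else 0.0})
    return pd.DataFrame(rows)
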