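"""Motif-anchored metagene profiles.

For a set of anchor codons (e.g. the P-site codons of +X+ or PDX motifs),
the metagene profile is the elementwise average of per-anchor rpm windows,
each window first normalized to sum to 1 so every site contributes equally.
Offsets run from -window/2 to +window/2 - 1 nt relative to the first
nucleotide of the anchor codon; anchors whose window does not fit inside
their ORF are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import RpmTrack

logger = logging.getLogger("ribostall")


@dataclass
class MetageneProfile:
    offsets: np.ndarray
    mean_density: np.ndarray
    n_anchors: int


def metagene_profile(
    rpm_track: RpmTrack,
    anchors: list[tuple[str, int]],
    window: int = 100,
) -> MetageneProfile:
    """Average window-normalized rpm around anchor codons.

    Anchors are (orf_id, codon_index); windows with zero total rpm are
    skipped (counted and logged), as are anchors too close to an ORF edge
    for the full window to fit.
    """
    if window < 6 or window % 2:
        raise ValueError("window must be even and >= 6")
    half = window // 2
    slices = []
    n_skipped_edge = n_skipped_zero = 0
    for orf_id, codon_index in anchors:
        rpm = rpm_track.rpm.get(orf_id)
        if rpm is None:
            n_skipped_edge += 1
            continue
        center = 3 * codon_index
        lo, hi = center - half, center + half
        if lo < 0 or hi > len(rpm):
            n_skipped_edge += 1
            continue
        win = rpm[lo:hi]
        total = win.sum()
        if total == 0:
            n_skipped_zero += 1
            continue
        slices.append(win / total)
    if not slices:
        raise ValueError("no usable anchors for metagene profile")
    if n_skipped_edge or n_skipped_zero:
        logger.info(
            "metagene: %d anchors skipped at ORF edges, %d with zero window signal",
            n_skipped_edge,
            n_skipped_zero,
        )
    mean = np.mean(slices, axis=0)
    return MetageneProfile(np.arange(-half, half), mean, len(slices))


def shared_anchors(
    rpm_tracks: list[RpmTrack],
    anchors: list[tuple[str, int]],
    window: int = 100,
) -> list[tuple[str, int]]:
    """Anchors usable in every track: window fits the ORF and has signal.

    Filtering jointly before profiling keeps the anchor set identical across
    conditions, which :func:`metagene_ratio` requires.
    """
    half = window // 2
    keep = []
    for orf_id, codon_index in anchors:
        center = 3 * codon_index
        ok = True
        for track in rpm_tracks:
            rpm = track.rpm.get(orf_id)
            if rpm is None or center - half < 0 or center + half > len(rpm):
                ok = False
                break
            if rpm[center - half : center + half].sum() == 0:
                ok = False
                break
        if ok:
            keep.append((orf_id, codon_index))
    return keep


def average_profiles(profiles: list[MetageneProfile]) -> MetageneProfile:
    """Replicate-level mean of metagene profiles (equal replicate weight)."""
    if not profiles:
        raise ValueError("no profiles to average")
    base = profiles[0].offsets
    for p in profiles[1:]:
        if not np.array_equal(p.offsets, base):
            raise ValueError("profiles have different offset grids")
    mean = np.mean([p.mean_density for p in profiles], axis=0)
    return MetageneProfile(base.copy(), mean, min(p.n_anchors for p in profiles))


def metagene_ratio(treated: MetageneProfile, control: MetageneProfile) -> np.ndarray:
    """Per-offset treated/control density ratio; NaN where control is zero.

    Both profiles must come from the same anchor set (same offsets and
    anchor count), mirroring how drug/control metagene ratios are formed.
    """
    if not np.array_equal(treated.offsets, control.offsets):
        raise ValueError("offset grids differ; compute both profiles from one anchor set")
    if treated.n_anchors != control.n_anchors:
        raise ValueError("anchor sets differ between conditions")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(control.mean_density > 0, treated.mean_density / control.mean_density, np.nan)
    return ratio


def metagene_table(
    offsets: np.ndarray,
    treated: MetageneProfile,
    control: MetageneProfile,
) -> pd.DataFrame:
    """Metagene TSV layout: offset, per-condition mean density, ratio."""
    return pd.DataFrame(
        {
            "offset": offsets,
            "treated": treated.mean_density,
            "control": control.mean_density,
            "ratio": metagene_ratio(treated, control),
        }
    )
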