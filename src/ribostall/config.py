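"""Pipeline-wide configuration.

All thresholds that control the analysis live in a single
:class:`PipelineConfig` so that every stage of the pipeline (track building,
pause statistics, site selection, logos, metagene) reads its knobs from one
validated place.  Defaults reproduce the published telithromycin analysis:
25–34 nt footprints, a fixed 18 nt 3'-end P-site offset, an rpm >= 0.5
nucleotide inclusion rule, >= 2.5-fold strong-arrest and >= 2-fold
least-sensitive thresholds applied in every replicate pair, a 100 nt metagene
window and Bonferroni-corrected alpha = 0.05 for logo significance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and switches controlling every pipeline stage.

    Attributes
    ----------
    psite_offset:
        Distance (nt) from the footprint 3' end to the P-site nucleotide.
    min_len, max_len:
        Inclusive footprint-length window; reads outside it are discarded.
    inclusion_threshold:
        Minimum per-nucleotide signal for a nucleotide to enter
        treated/control ratio computation (units set by ``inclusion_units``).
    inclusion_units:
        ``"rpm"`` (default) applies the cutoff to rpm; ``"pause"`` applies it
        to the nucleotide pause score instead.
    strong_fold:
        Fold-increase (treated/control codon pause score) required in every
        replicate pair for a strong arrest site.
    weak_fold:
        Fold-decrease required in every replicate pair for a least-sensitive
        ("weak") site; the rule is ratio <= 1/weak_fold.
    metagene_window:
        Width (nt, even) of the motif-anchored metagene window.
    min_gene_rpkm:
        Genes below this rpkm in any sample are flagged inactive and excluded.
    alpha:
        Logo significance level before Bonferroni correction over
        20 residues x 10 positions.
    unique_orf:
        If True, reads whose P-site falls in more than one ORF are dropped
        rather than counted in each.
    trim_codons:
        Number of codons trimmed from each ORF end before ratio computation
        (0 = no trimming, matching the published analysis).
    exclude_orf_start_windows:
        If True, drop sites with P-site codon index < 9 so every context
        window is complete (removes the initiator-Met artifact at -8).
    weak_all_replicates:
        Require the weak-site rule in every replicate pair (default) or in
        any single pair.
    average_replicate_profiles:
        Metagene replicate handling: average per-replicate profiles (default)
        or pool rpm before profiling.
    random_seed:
        Seed for every stochastic component (synthetic data).
    """

    psite_offset: int = 18
    min_len: int = 25
    max_len: int = 34
    inclusion_threshold: float = 0.5
    inclusion_units: str = "rpm"
    strong_fold: float = 2.5
    weak_fold: float = 2.0
    metagene_window: int = 100
    min_gene_rpkm: float = 5.0
    alpha: float = 0.05
    unique_orf: bool = False
    trim_codons: int = 0
    exclude_orf_start_windows: bool = False
    weak_all_replicates: bool = True
    average_replicate_profiles: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(
                f"min_len ({self.min_len}) must be <= max_len ({self.max_len})"
            )
        for name in (
            "inclusion_threshold",
            "strong_fold",
            "weak_fold",
            "min_gene_rpkm",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.psite_offset < 0:
            raise ValueError("psite_offset must be >= 0")
        if self.metagene_window < 6 or self.metagene_window % 2:
            raise ValueError("metagene_window must be even and >= 6")
        if self.inclusion_units not in ("rpm", "pause"):
            raise ValueError("inclusion_units must be 'rpm' or 'pause'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()
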