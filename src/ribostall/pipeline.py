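"""End-to-end orchestration: tracks -> pause ratios -> sites -> logos -> metagene.

Every number in every report is reproducible by calling the library
operations directly; this module only sequences them, writes TSV outputs and
records a run manifest.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import OrfRecord, load_orfs
from .config import DEFAULT_CONFIG, PipelineConfig
from .logo import build_logo, class_summary, classify_context, condition_on
from .metagene import average_profiles, metagene_profile, metagene_ratio, shared_anchors
from .pause import build_ratio_table, gene_score_table
from .selection import background_universe, select_strong_sites, select_weak_sites, sites_table
from .simulate import (
    SyntheticSpec,
    evaluate_recovery,
    make_genome,
    simulate_tracks,
    write_genome_files,
    write_track_bedgraphs,
)
from .tracks import RpmTrack, SampleTrack, build_track, normalize_rpm

logger = logging.getLogger("ribostall")


@dataclass
class Sample:
    """One row of the sample table.

    ``path`` is a BAM file, or a (plus, minus) bedGraph pair for the 3'-end
    count dialect.
    """

    sample_id: str
    condition: str
    replicate: int
    path: str | tuple[str, str]

    def files(self) -> list[str]:
        return list(self.path) if isinstance(self.path, (tuple, list)) else [self.path]


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_samples(samples: list[Sample]) -> None:
    conditions = {s.condition for s in samples}
    if "treated" not in conditions:
        raise ValueError("no treated condition in sample table")
    if "control" not in conditions:
        raise ValueError("no control condition in sample table")
    for s in samples:
        for f in s.files():
            if not Path(f).exists():
                raise FileNotFoundError(f"sample {s.sample_id}: missing input file {f}")


def _logo_or_none(fg, bg, alpha):
    try:
        return build_logo(fg, bg, alpha)
    except ValueError as exc:
        logger.warning("logo skipped: %s", exc)
        return None


def run_pipeline(
    genome: str | Path,
    annotation: str | Path,
    samples: list[Sample],
    outdir: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    orfs: list[OrfRecord] | None = None,
    tracks: dict[str, SampleTrack] | None = None,
    check_edges: bool = True,
) -> dict:
    """Run the full analysis and write TSV reports into ``outdir``.

    Returns a dict of in-memory results (ratio table, sites, logos, metagene
    tables, class summary) for programmatic use.  ``orfs``/``tracks`` may be
    supplied to skip re-parsing when chained from the simulator.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate_samples(samples)

    if orfs is None:
        orfs = load_orfs(genome, annotation, check_edges=check_edges)
    logger.info("loaded %d ORFs", len(orfs))

    if tracks is None:
        tracks = {}
        for s in samples:
            path = tuple(s.path) if isinstance(s.path, (tuple, list)) else s.path
            tracks[s.sample_id] = build_track(
                path, orfs, s.condition, s.replicate, sample_id=s.sample_id, config=config
            )
            logger.info(
                "sample %s: %d assigned footprints", s.sample_id, tracks[s.sample_id].total_mapped
            )
    rpm_tracks: dict[str, RpmTrack] = {sid: normalize_rpm(t) for sid, t in tracks.items()}

    gene_df = gene_score_table(rpm_tracks, orfs, config)
    gene_df.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)

    table = build_ratio_table(rpm_tracks, orfs, config)
    table.to_csv(outdir / "pause_ratios.tsv", sep="\t", index=False)

    strong = select_strong_sites(table, orfs, config, allow_single_replicate=True)
    weak = select_weak_sites(table, orfs, config, allow_single_replicate=True)
    for site in strong + weak:
        site.motif_class = classify_context(site.context)
    all_sites = sites_table(strong + weak)
    all_sites.to_csv(outdir / "stall_sites.tsv", sep="\t", index=False)

    summary = class_summary([s.motif_class for s in strong])
    summary.to_csv(outdir / "motif_classes.tsv", sep="\t", index=False)

    background = background_universe(table, orfs, config)
    fg_all = [s.context for s in strong]
    logos = {"all": _logo_or_none(fg_all, background, config.alpha)}
    if fg_all and background:
        try:
            fg_x = condition_on(condition_on(fg_all, -1, "KR"), 1, "KR")
            bg_x = condition_on(condition_on(background, -1, "KR"), 1, "KR")
            logos["xplus"] = _logo_or_none(fg_x, bg_x, config.alpha)
        except ValueError as exc:
            logger.warning("+X+ conditioned logo skipped: %s", exc)
        try:
            fg_p = condition_on(fg_all, -1, "P")
            bg_p = condition_on(background, -1, "P")
            logos["pxx"] = _logo_or_none(fg_p, bg_p, config.alpha)
        except ValueError as exc:
            logger.warning("Pro-conditioned logo skipped: %s", exc)
    for name, logo in logos.items():
        if logo is not None:
            logo.table.to_csv(outdir / f"logo_{name}.tsv", sep="\t", index=False)

    metagene_tables = {}
    treated_tracks = sorted(
        (t for t in rpm_tracks.values() if t.condition == "treated"), key=lambda t: t.replicate
    )
    control_tracks = sorted(
        (t for t in rpm_tracks.values() if t.condition == "control"), key=lambda t: t.replicate
    )
    for cls, tag in (("+X+", "xplus"), ("PDX", "pdx")):
        anchors = [(s.orf_id, s.codon_index) for s in strong if s.motif_class == cls]
        anchors = shared_anchors(list(rpm_tracks.values()), anchors, config.metagene_window)
        if not anchors:
            logger.info("no usable %s anchors for metagene", cls)
            continue
        if config.average_replicate_profiles:
            prof_t = average_profiles(
                [metagene_profile(t, anchors, config.metagene_window) for t in treated_tracks]
            )
            prof_c = average_profiles(
                [metagene_profile(t, anchors, config.metagene_window) for t in control_tracks]
            )
        else:
            pooled_t = _pool_rpm(treated_tracks)
            pooled_c = _pool_rpm(control_tracks)
            prof_t = metagene_profile(pooled_t, anchors, config.metagene_window)
            prof_c = metagene_profile(pooled_c, anchors, config.metagene_window)
        df = pd.DataFrame(
            {
                "offset": prof_t.offsets,
                "treated": prof_t.mean_density,
                "control": prof_c.mean_density,
                "ratio": metagene_ratio(prof_t, prof_c),
            }
        )
        df.to_csv(outdir / f"metagene_{tag}.tsv", sep="\t", index=False)
        metagene_tables[cls] = df

    manifest = {
        "tool": "ribostall",
        "version": __version__,
        "seed": config.random_seed,
        "config": config.to_dict(),
        "samples": [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "replicate": s.replicate,
                "path": list(s.files()),
                "md5": [_checksum(f) for f in s.files()],
            }
            for s in samples
        ],
        "inputs": {
            "genome": str(genome),
            "annotation": str(annotation),
        },
        "n_orfs": len(orfs),
        "n_ratio_sites": int(len(table)),
        "n_strong_sites": len(strong),
        "n_weak_sites": len(weak),
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    logger.info("pipeline finished in %.1f s", manifest["runtime_s"])
    return {
        "orfs": orfs,
        "tracks": tracks,
        "rpm_tracks": rpm_tracks,
        "gene_scores": gene_df,
        "ratio_table": table,
        "strong_sites": strong,
        "weak_sites": weak,
        "background": background,
        "logos": logos,
        "class_summary": summary,
        "metagene": metagene_tables,
        "manifest": manifest,
    }


def _pool_rpm(tracks: list[RpmTrack]) -> RpmTrack:
    base = tracks[0]
    pooled = {k: sum(t.rpm[k] for t in tracks) / len(tracks) for k in base.rpm}
    return RpmTrack(f"pooled_{base.condition}", base.condition, 0, pooled, base.total_mapped)


def simulate_and_run(
    spec: SyntheticSpec,
    outdir: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    """Chain: synthetic genome -> bedGraph tracks -> full pipeline -> recovery.

    The simulated tracks are written to disk as FASTA/GFF3/bedGraph and read
    back through the standard input path, so the synthetic run exercises the
    same readers as real data.  Returns the pipeline results plus a
    ``recovery`` report against the planted truth table.
    """
    outdir = Path(outdir)
    genome = make_genome(spec)
    if genome.truth.empty:
        raise ValueError("synthetic spec plants no sites; recovery is undefined")
    paths = write_genome_files(genome, outdir / "inputs")
    tracks = simulate_tracks(spec, genome)
    samples = []
    for sid, track in sorted(tracks.items()):
        plus, minus = write_track_bedgraphs(track, genome, outdir / "inputs", config.psite_offset)
        samples.append(Sample(sid, track.condition, track.replicate, (str(plus), str(minus))))
    results = run_pipeline(
        paths["fasta"], paths["gff3"], samples, outdir, config, check_edges=True
    )
    recovery = evaluate_recovery(results["strong_sites"], genome.truth)
    (outdir / "recovery.yaml").write_text(yaml.safe_dump(recovery, sort_keys=False))
    results["recovery"] = recovery
    results["truth"] = genome.truth
    return results
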