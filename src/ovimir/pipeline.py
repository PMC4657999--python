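"""End-to-end orchestration of the characterization stages.

``run_pipeline`` executes, in order: score-cutoff selection and candidate
filtering; conservation tiering, naming and family grouping; library
specificity, arm preference, same-mature grouping, genomic clustering and
chromosomal density; isomiR classification; and no-replicate fold change —
then writes per-stage TSVs and a JSON summary.  The pipeline is a pure
function of its inputs and configuration: identical reruns produce
identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from . import io as ovio
from .arms import arm_profile, count_arm_switches, duplicate_groups
from .conservation import assign_tier, assign_names, group_families
from .filtering import apply_candidate_filters, select_score_cutoff
from .genome import chromosome_summary, classify_specificity, detect_clusters
from .isomir import summarize_isomirs
from .model import ConfigurationError, Precursor, ReadStack, total_count
from .quantify import NormalizationError, fold_change, size_factors
from .report import as_percent, length_distribution

logger = logging.getLogger("ovimir")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_inputs"]

DEFAULTS = dict(
    libraries=("LV", "GL"),
    min_snr=10.0,
    min_count=10,
    max_genome_hits=5,
    genome_evalue=2e-08,
    broad_e=4e-09,
    narrow_e=9e-05,
    single_e=2e-04,
    max_gap=10_000,
    include_known_clusters=True,
    species_prefix="oar",
    length_band=(18, 24),
)


@dataclass
class PipelineConfig:
    """Thresholds for every stage; zero-config defaults are the values of
    the study this package characterizes."""

    libraries: tuple[str, str] = DEFAULTS["libraries"]
    min_snr: float = DEFAULTS["min_snr"]
    min_count: int = DEFAULTS["min_count"]
    max_genome_hits: int = DEFAULTS["max_genome_hits"]
    genome_evalue: float = DEFAULTS["genome_evalue"]
    broad_e: float = DEFAULTS["broad_e"]
    narrow_e: float = DEFAULTS["narrow_e"]
    single_e: float = DEFAULTS["single_e"]
    max_gap: int = DEFAULTS["max_gap"]
    include_known_clusters: bool = DEFAULTS["include_known_clusters"]
    species_prefix: str = DEFAULTS["species_prefix"]
    length_band: tuple[int, int] = DEFAULTS["length_band"]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(mapping) - set(DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("libraries", "length_band"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class Inputs:
    precursors: list[Precursor]
    stacks: dict[str, ReadStack]
    hits: list
    chrom_lengths: dict[str, int]
    snr_rows: list[tuple[float, float]]
    homolog_catalog: dict[str, str]


def load_inputs(indir: str | Path) -> Inputs:
    """Load every canonical file from one directory (names as emitted by
    the synthetic generator)."""
    indir = Path(indir)
    return Inputs(
        precursors=ovio.read_precursor_table(indir / "precursors.tsv"),
        stacks=ovio.read_read_stacks(indir / "read_stacks.tsv"),
        hits=ovio.read_homology_hits(indir / "homology.tsv"),
        chrom_lengths=ovio.read_chrom_lengths(indir / "chrom_lengths.tsv"),
        snr_rows=ovio.read_snr_table(indir / "snr.tsv"),
        homolog_catalog=ovio.read_fasta(indir / "homolog_matures.fasta"),
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    score_cutoff: float
    filter_report: Any
    kept: list[Precursor]
    calls: dict
    names: dict[str, str]
    families: dict[str, list[str]]
    specificity: Any
    arm_profiles: list
    arm_switches: int
    duplicate_groups: dict[str, list[str]]
    clusters: list
    chrom_summary: Any
    isomir_distribution: Any
    fold_changes: dict[str, float]
    size_factors: dict[str, float]
    length_histogram: dict[int, int]
    length_band_fraction: float
    summary: dict[str, Any]


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    inputs: Inputs,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    lib_a, lib_b = cfg.libraries

    t = _stage("filtering")
    if inputs.snr_rows:
        cutoff = select_score_cutoff(inputs.snr_rows, min_snr=cfg.min_snr)
    else:
        cutoff = -math.inf
    report = apply_candidate_filters(
        inputs.precursors,
        inputs.stacks,
        inputs.hits,
        score_cutoff=cutoff,
        min_count=cfg.min_count,
        max_genome_hits=cfg.max_genome_hits,
        genome_evalue=cfg.genome_evalue,
    )
    kept_ids = set(report.kept)
    kept = [p for p in inputs.precursors if p.id in kept_ids]
    kept_novel = [p for p in kept if not p.is_known]
    for pid, reason in sorted(report.dropped.items()):
        logger.info("dropped %s: %s", pid, reason)
    logger.info("filtering done in %.2fs", time.perf_counter() - t)

    t = _stage("conservation and naming")
    calls = {
        p.id: assign_tier(
            p.id,
            inputs.hits,
            broad_e=cfg.broad_e,
            narrow_e=cfg.narrow_e,
            single_e=cfg.single_e,
        )
        for p in kept_novel
    }
    names = assign_names(
        kept_novel,
        calls,
        inputs.homolog_catalog,
        species_prefix=cfg.species_prefix,
    ) if kept_novel else {}
    for p in kept_novel:
        p.name = names.get(p.id)
    families = group_families(names)
    logger.info("conservation done in %.2fs", time.perf_counter() - t)

    t = _stage("specificity, arms, clusters, density")
    specificity = classify_specificity(kept_novel, cfg.libraries, cfg.min_count)
    profiles = [
        arm_profile(p, cfg.libraries, cfg.min_count) for p in kept_novel
    ]
    switches = count_arm_switches(profiles)
    dup_groups = duplicate_groups(kept_novel)
    clusters = detect_clusters(
        kept, max_gap=cfg.max_gap, include_known=cfg.include_known_clusters
    )
    chrom = chromosome_summary(kept, inputs.chrom_lengths)
    logger.info("characterization done in %.2fs", time.perf_counter() - t)

    t = _stage("isomiR classification")
    kept_stacks = {pid: s for pid, s in inputs.stacks.items() if pid in kept_ids}
    distribution = summarize_isomirs(kept_stacks, kept)
    logger.info("isomiRs done in %.2fs", time.perf_counter() - t)

    t = _stage("quantification")
    matrix = {}
    for p in kept:
        for m in p.matures:
            feature = f"{p.id}-{m.arm}"
            matrix[feature] = {lib: m.count(lib) for lib in cfg.libraries}
    try:
        factors = size_factors(matrix, cfg.libraries) if matrix else {}
        fcs = fold_change(matrix, factors, cfg.libraries) if factors else {}
    except NormalizationError:
        factors, fcs = {}, {}
    all_reads = [r for s in kept_stacks.values() for r in s.reads]
    if all_reads:
        histogram, band_fraction = length_distribution(all_reads, cfg.length_band)
    else:
        histogram, band_fraction = {}, float("nan")
    logger.info("quantification done in %.2fs", time.perf_counter() - t)

    tier_counts: dict[str, int] = {}
    for call in calls.values():
        tier_counts[call.tier] = tier_counts.get(call.tier, 0) + 1
    summary = {
        "score_cutoff": cutoff if cutoff != -math.inf else None,
        "n_input": len(inputs.precursors),
        "n_kept": len(report.kept),
        "n_dropped": len(report.dropped),
        "drop_reasons": _reason_counts(report.dropped),
        "specificity_precursors": specificity.precursor_totals,
        "specificity_matures": specificity.mature_totals,
        "tier_counts": tier_counts,
        "n_families": len(families),
        "arm_switches": switches,
        "duplicate_mature_groups": len(dup_groups),
        "n_clusters": len(clusters),
        "cluster_members": sorted(c.member_ids for c in clusters),
        "isomir_pooled": distribution.pooled,
        "isomir_per_library": distribution.per_library,
        "size_factors": factors,
        "length_band": list(cfg.length_band),
        "length_band_fraction": band_fraction,
        "length_band_percent": (
            round(100 * band_fraction, 2) if band_fraction == band_fraction else None
        ),
    }

    result = PipelineResult(
        config=cfg,
        score_cutoff=cutoff,
        filter_report=report,
        kept=kept,
        calls=calls,
        names=names,
        families=families,
        specificity=specificity,
        arm_profiles=profiles,
        arm_switches=switches,
        duplicate_groups=dup_groups,
        clusters=clusters,
        chrom_summary=chrom,
        isomir_distribution=distribution,
        fold_changes=fcs,
        size_factors=factors,
        length_histogram=histogram,
        length_band_fraction=band_fraction,
        summary=summary,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _reason_counts(dropped: Mapping[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for reason in dropped.values():
        out[reason] = out.get(reason, 0) + 1
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = [{"id": pid, "status": "kept", "reason": ""} for pid in result.filter_report.kept]
    rows += [
        {"id": pid, "status": "dropped", "reason": reason}
        for pid, reason in sorted(result.filter_report.dropped.items())
    ]
    pd.DataFrame(rows, columns=["id", "status", "reason"]).to_csv(
        outdir / "filter_report.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [
            {
                "precursor_id": pid,
                "tier": call.tier,
                "n_species": len(call.supporting_species),
                "species": ",".join(sorted(call.supporting_species)),
                "name": result.names.get(pid, ""),
            }
            for pid, call in sorted(result.calls.items())
        ]
    ).to_csv(outdir / "conservation.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"precursor_id": c.precursor_id, "specificity": c.specificity}
            for c in result.specificity.calls
        ]
    ).to_csv(outdir / "specificity.tsv", sep="\t", index=False)

    libs = result.config.libraries
    pd.DataFrame(
        [
            {
                "precursor_id": p.precursor_id,
                **{
                    f"expressed_{lib}": ",".join(sorted(p.expressed_arms.get(lib, ())))
                    for lib in libs
                },
                **{
                    f"dominant_{lib}": p.dominant_arm.get(lib) or ""
                    for lib in libs
                },
                "switch": p.switch_flag,
            }
            for p in result.arm_profiles
        ]
    ).to_csv(outdir / "arm_profiles.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "chrom": chrom,
                "known": known,
                "novel": novel,
                "density_per_mbp": density,
                "density_2dp": round(density, 2),
            }
            for chrom, (known, novel, density) in result.chrom_summary.per_chrom.items()
        ]
    ).to_csv(outdir / "chromosome_summary.tsv", sep="\t", index=False)

    ovio.write_bed(result.clusters, outdir / "clusters.bed")

    pd.DataFrame(
        [
            {"feature": feat, "fold_change": fc}
            for feat, fc in sorted(result.fold_changes.items())
        ]
    ).to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)

    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, sort_keys=True, default=str)
    )
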