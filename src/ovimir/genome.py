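"""Library specificity, genomic clustering, and chromosomal distribution.

A precursor is present in a library when any of its mature forms reaches
the read-count floor there; presence across an ordered library pair yields
the specificity classes A-only / B-only / both.  A cluster is a maximal
same-strand chain of precursors whose adjacent genomic gaps are below a
threshold (default 10 kb) — such groups are often transcribed as one
polycistronic primary transcript.  Chromosome summaries report known/novel
counts and density in miRNAs per Mbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    ConfigurationError,
    GenomicInterval,
    Precursor,
    ValidationError,
)

__all__ = [
    "SpecificityCall",
    "SpecificityResult",
    "Cluster",
    "ChromSummary",
    "classify_specificity",
    "detect_clusters",
    "chromosome_summary",
]

SPECIFICITY_CLASSES = ("A_only", "B_only", "both")


@dataclass(frozen=True)
class SpecificityCall:
    precursor_id: str
    specificity: str

    def __post_init__(self) -> None:
        if self.specificity not in SPECIFICITY_CLASSES:
            raise ValidationError(f"unknown specificity class {self.specificity!r}")


@dataclass
class SpecificityResult:
    """Per-precursor calls plus the partition totals for precursors and
    mature forms (the two rows of a library-specificity summary table)."""

    calls: list[SpecificityCall]
    precursor_totals: dict[str, int]
    mature_totals: dict[str, int]
    absent: list[str] = field(default_factory=list)

    def total_precursors(self) -> int:
        return sum(self.precursor_totals.values())

    def total_matures(self) -> int:
        return sum(self.mature_totals.values())


def _presence_class(count_a: int, count_b: int, min_count: int) -> Optional[str]:
    in_a, in_b = count_a >= min_count, count_b >= min_count
    if in_a and in_b:
        return "both"
    if in_a:
        return "A_only"
    if in_b:
        return "B_only"
    return None


def classify_specificity(
    precursors: Sequence[Precursor],
    libraries: Sequence[str],
    min_count: int = 10,
) -> SpecificityResult:
    """Classify presence across an ordered library pair (A, B).

    A precursor is present in a library when any mature form has count >=
    ``min_count`` there.  Precursors absent from both libraries are
    excluded from the partition and listed in ``absent``.  Mature forms are
    classified individually by their own counts.
    """
    if len(libraries) != 2:
        raise ConfigurationError("specificity needs an ordered pair of libraries")
    lib_a, lib_b = libraries
    calls: list[SpecificityCall] = []
    absent: list[str] = []
    prec_totals = dict.fromkeys(SPECIFICITY_CLASSES, 0)
    mat_totals = dict.fromkeys(SPECIFICITY_CLASSES, 0)
    for p in precursors:
        for m in p.matures:
            m_cls = _presence_class(m.count(lib_a), m.count(lib_b), min_count)
            if m_cls is not None:
                mat_totals[m_cls] += 1
        cls = _presence_class(
            max((m.count(lib_a) for m in p.matures), default=0),
            max((m.count(lib_b) for m in p.matures), default=0),
            min_count,
        )
        if cls is None:
            absent.append(p.id)
        else:
            calls.append(SpecificityCall(p.id, cls))
            prec_totals[cls] += 1
    return SpecificityResult(
        calls=calls,
        precursor_totals=prec_totals,
        mature_totals=mat_totals,
        absent=absent,
    )


@dataclass
class Cluster:
    """A maximal same-strand chain of precursors with sub-threshold gaps."""

    members: list[Precursor]
    interval: GenomicInterval = None  # envelope; derived in __post_init__

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a cluster needs at least two members")
        chroms = {p.interval.chrom for p in self.members}
        strands = {p.interval.strand for p in self.members}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValidationError("cluster members must share chromosome and strand")
        self.members = sorted(self.members, key=lambda p: p.interval.start)
        self.interval = GenomicInterval(
            chrom=chroms.pop(),
            start=min(p.interval.start for p in self.members),
            end=max(p.interval.end for p in self.members),
            strand=strands.pop(),
        )

    @property
    def member_ids(self) -> list[str]:
        return [p.id for p in self.members]


def detect_clusters(
    precursors: Iterable[Precursor],
    max_gap: int = 10_000,
    include_known: bool = True,
) -> list[Cluster]:
    """Chain same-strand precursors with inter-precursor gaps < ``max_gap``.

    The gap is measured between adjacent feature boundaries (previous
    envelope end to next start); overlapping precursors (negative gap)
    chain.  Chaining is transitive, so long runs form one cluster.  Only
    maximal chains of size >= 2 are returned.
    """
    pool = [p for p in precursors if include_known or not p.is_known]
    ids = [p.id for p in pool]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate precursor ids in cluster input")
    pool.sort(key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start))

    clusters: list[Cluster] = []
    chain: list[Precursor] = []
    chain_end = None
    for p in pool:
        if (
            chain
            and p.interval.chrom == chain[-1].interval.chrom
            and p.interval.strand == chain[-1].interval.strand
            and p.interval.start - chain_end < max_gap
        ):
            chain.append(p)
            chain_end = max(chain_end, p.interval.end)
        else:
            if len(chain) >= 2:
                clusters.append(Cluster(members=chain))
            chain = [p]
            chain_end = p.interval.end
    if len(chain) >= 2:
        clusters.append(Cluster(members=chain))
    return clusters


@dataclass
class ChromSummary:
    """Per-chromosome known/novel counts and density (miRNAs per Mbp)."""

    per_chrom: dict[str, tuple[int, int, float]]

    def density(self, chrom: str) -> float:
        return self.per_chrom[chrom][2]

    def rendered_density(self, chrom: str) -> float:
        """Density rendered at 2 decimals, as reported in summaries."""
        return round(self.per_chrom[chrom][2], 2)

    def mean_novel_per_chromosome(self) -> float:
        """Average novel-precursor count over all listed chromosomes."""
        n = len(self.per_chrom)
        return sum(v[1] for v in self.per_chrom.values()) / n if n else 0.0


def chromosome_summary(
    precursors: Iterable[Precursor],
    chrom_lengths: Mapping[str, int],
) -> ChromSummary:
    """Count known/novel precursors per chromosome and derive densities.

    Every chromosome in ``chrom_lengths`` appears in the summary (zero
    counts give zero density); a precursor on a chromosome missing from the
    length table is a validation error.
    """
    counts = {chrom: [0, 0] for chrom in chrom_lengths}
    for p in precursors:
        chrom = p.interval.chrom
        if chrom not in chrom_lengths:
            raise ValidationError(
                f"chromosome {chrom!r} (precursor {p.id}) missing from length table"
            )
        counts[chrom][1 if not p.is_known else 0] += 1
    per_chrom = {
        chrom: (
            known,
            novel,
            (known + novel) / (chrom_lengths[chrom] / 1e6),
        )
        for chrom, (known, novel) in counts.items()
    }
    return ChromSummary(per_chrom=per_chrom)
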