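"""Candidate-retention rules for hairpin discovery post-processing.

Novel candidates are kept only above a detection-score cutoff chosen from a
signal-to-noise table (the lowest cutoff whose estimated true:false call
ratio exceeds 10:1).  All candidates, known and novel, must carry at least
10 reads on some mature form.  Candidates resembling repeated genomic
sequence (more than five strong self-genome hits on distinct chromosomal
areas) or other small-RNA classes (snRNA/snoRNA/tRNA, via RefSeq/Rfam hits)
are removed.  Known precursors are exempt from the score rule only: their
hairpins are considered already validated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    HomologyHit,
    NoDataError,
    Precursor,
    ReadStack,
    ValidationError,
    total_count,
)

__all__ = ["SnrRow", "FilterReport", "select_score_cutoff", "apply_candidate_filters"]

DROP_REASONS = ("low_score", "low_count", "repeat", "other_ncrna")


@dataclass(frozen=True)
class SnrRow:
    """One row of the score-threshold selection table."""

    cutoff: float
    snr: float

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValidationError(f"SNR must be positive, got {self.snr}")


@dataclass
class FilterReport:
    """Partition of candidate ids into kept and dropped-with-reason."""

    kept: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise ValidationError(f"ids both kept and dropped: {sorted(overlap)}")


def select_score_cutoff(
    table: Sequence[SnrRow] | Sequence[tuple[float, float]],
    min_snr: float = 10.0,
) -> float:
    """Smallest score cutoff with signal-to-noise strictly above ``min_snr``."""
    rows = [r if isinstance(r, SnrRow) else SnrRow(*r) for r in table]
    if not rows:
        raise NoDataError("empty signal-to-noise table")
    cutoffs = [r.cutoff for r in rows]
    if len(set(cutoffs)) != len(cutoffs):
        raise ValidationError("duplicate cutoffs in signal-to-noise table")
    admissible = [r.cutoff for r in rows if r.snr > min_snr]
    if not admissible:
        raise NoDataError(
            f"no admissible cutoff: no row has signal-to-noise > {min_snr}"
        )
    return min(admissible)


_LOCATED_SUBJECT_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _distinct_genomic_areas(subject_ids: Iterable[str]) -> int:
    """Count distinct (non-overlapping) genomic areas among hit subjects.

    Subject ids of the form ``chrom:start-end`` are merged when they overlap
    on the same chromosome; any other subject id counts as its own area.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    opaque: set[str] = set()
    for sid in subject_ids:
        m = _LOCATED_SUBJECT_RE.match(sid)
        if m:
            intervals.setdefault(m["chrom"], []).append(
                (int(m["start"]), int(m["end"]))
            )
        else:
            opaque.add(sid)
    n = len(opaque)
    for chrom_ivs in intervals.values():
        chrom_ivs.sort()
        merged_end = None
        for start, end in chrom_ivs:
            if merged_end is None or start >= merged_end:
                n += 1
                merged_end = end
            else:
                merged_end = max(merged_end, end)
    return n


def _mature_totals(precursor: Precursor, stack: Optional[ReadStack]) -> list[int]:
    """Total read count per mature form, from the table or (fallback) the stack."""
    totals = []
    for m in precursor.matures:
        t = total_count(m.counts)
        if t == 0 and stack is not None:
            t = sum(
                r.count
                for r in stack.reads
                if r.start < m.end and r.end > m.offset
            )
        totals.append(t)
    return totals


def apply_candidate_filters(
    precursors: Sequence[Precursor],
    stacks: Mapping[str, ReadStack] | None = None,
    hits: Iterable[HomologyHit] = (),
    *,
    score_cutoff: float,
    min_count: int = 10,
    max_genome_hits: int = 5,
    genome_evalue: float = 2e-08,
    other_ncrna_evalue: float | None = None,
) -> FilterReport:
    """Apply the retention rules in order, recording one reason per drop.

    Order: (1) ``low_score`` — novel precursors scoring below the cutoff
    (known precursors are exempt); (2) ``low_count`` — no mature form
    reaches ``min_count`` total reads over libraries; (3) ``repeat`` — more
    than ``max_genome_hits`` self-genome hits below ``genome_evalue`` on
    distinct genomic areas; (4) ``other_ncrna`` — any RefSeq/Rfam hit below
    the screening E-value (defaults to ``genome_evalue``).
    """
    if min_count < 0 or max_genome_hits < 0 or genome_evalue <= 0:
        raise ValidationError("filter thresholds must be nonnegative (E-value > 0)")
    if other_ncrna_evalue is None:
        other_ncrna_evalue = genome_evalue
    stacks = stacks or {}

    ids = [p.id for p in precursors]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate precursor ids in filter input")

    genome_subjects: dict[str, list[str]] = {}
    ncrna_flag: set[str] = set()
    for h in hits:
        if h.db == "genome_self" and h.evalue < genome_evalue:
            genome_subjects.setdefault(h.query_id, []).append(h.subject_id)
        elif h.db == "rfam_refseq" and h.evalue < other_ncrna_evalue:
            ncrna_flag.add(h.query_id)

    report = FilterReport()
    for p in precursors:
        if not p.is_known and p.score < score_cutoff:
            report.dropped[p.id] = "low_score"
        elif not any(
            t >= min_count for t in _mature_totals(p, stacks.get(p.id))
        ):
            report.dropped[p.id] = "low_count"
        elif (
            _distinct_genomic_areas(genome_subjects.get(p.id, ())) > max_genome_hits
        ):
            report.dropped[p.id] = "repeat"
        elif p.id in ncrna_flag:
            report.dropped[p.id] = "other_ncrna"
        else:
            report.kept.append(p.id)
    return report
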