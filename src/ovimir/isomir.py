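"""isomiR classification against a reference mature sequence.

Sequenced miRNA reads rarely all match the annotated mature exactly:
imprecise Drosha/Dicer cleavage yields 5'- and 3'-shifted variants, the 3'
end is frequently extended by non-genomic nucleotides (mostly A/U), and
editing produces internal substitutions.  Each read overlapping the mature
interval is placed in exactly one category:

* ``reference`` — identical to the mature at its position;
* ``templated_5p`` / ``templated_3p`` — one end shifted (extended,
  truncated, or both) with every extending base matching the hairpin;
* ``nontemplated_5p`` / ``nontemplated_3p`` — one end extended with at
  least one base that does not match the hairpin;
* ``both_ends_templated`` / ``both_ends_nontemplated`` — both ends variant;
* ``polymorphic`` — internal substitution(s) within the read/hairpin body
  (takes precedence over end variation so the categories are exclusive).

Reads that do not overlap the mature (star- or loop-derived) are excluded
from distributions and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    AlignedRead,
    MatureForm,
    NoDataError,
    Precursor,
    ReadStack,
    ValidationError,
)

__all__ = [
    "CATEGORIES",
    "IsomirCall",
    "IsomirDistribution",
    "UnassignedReadError",
    "classify_read",
    "dominant_form",
    "summarize_isomirs",
]

CATEGORIES = (
    "reference",
    "templated_5p",
    "nontemplated_5p",
    "templated_3p",
    "nontemplated_3p",
    "both_ends_templated",
    "both_ends_nontemplated",
    "polymorphic",
)

SEED_START = 2  # 1-based mature positions delimiting the seed
SEED_END = 8


class UnassignedReadError(ValueError):
    """The read does not overlap the mature interval (star/loop read)."""


@dataclass(frozen=True)
class IsomirCall:
    """Classification of one read against one reference mature."""

    category: str
    five_prime_offset: int  # read start - mature start; negative = extension
    three_prime_offset: int  # read end - mature end; positive = extension
    substitutions: frozenset[int] = frozenset()  # 1-based mature positions
    seed_affected: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown isomiR category {self.category!r}")
        if self.category == "reference" and (
            self.five_prime_offset or self.three_prime_offset or self.substitutions
        ):
            raise ValidationError("reference call must have no offsets/substitutions")


def classify_read(
    read: AlignedRead, mature: MatureForm, precursor_seq: str
) -> IsomirCall:
    """Classify one aligned read against the reference mature.

    The read must overlap the mature interval on the precursor; otherwise
    :class:`UnassignedReadError` is raised and the caller excludes the read
    from the distribution.
    """
    m0, m1 = mature.offset, mature.end
    r0, r1 = read.start, read.end
    if r1 <= m0 or r0 >= m1:
        raise UnassignedReadError(
            f"read at [{r0}, {r1}) does not overlap mature [{m0}, {m1})"
        )

    five_offset = r0 - m0
    three_offset = r1 - m1

    mismatch_pos = {pos for pos, _ in read.mismatches}

    def base_nontemplated(read_pos_1b: int) -> bool:
        prec_pos = r0 + read_pos_1b - 1
        if prec_pos < 0 or prec_pos >= len(precursor_seq):
            return True  # aligned past the hairpin: no template base exists
        return read_pos_1b in mismatch_pos

    # Extending bases: read positions aligned outside the mature interval.
    five_nontemplated = False
    if five_offset < 0:  # 5' extension
        five_nontemplated = any(
            base_nontemplated(i) for i in range(1, -five_offset + 1)
        )
    three_nontemplated = False
    if three_offset > 0:  # 3' extension
        n = len(read.sequence)
        three_nontemplated = any(
            base_nontemplated(i) for i in range(n - three_offset + 1, n + 1)
        )

    # Internal substitutions: mismatches within both the read and the
    # hairpin body, excluding extension bases beyond the mature ends.
    substitutions = set()
    for pos in mismatch_pos:
        prec_pos = r0 + pos - 1
        if 0 <= prec_pos < len(precursor_seq) and m0 <= prec_pos < m1:
            substitutions.add(prec_pos - m0 + 1)  # 1-based mature position

    if substitutions:
        category = "polymorphic"
    elif five_offset != 0 and three_offset != 0:
        category = (
            "both_ends_nontemplated"
            if (five_nontemplated or three_nontemplated)
            else "both_ends_templated"
        )
    elif five_offset != 0:
        category = "nontemplated_5p" if five_nontemplated else "templated_5p"
    elif three_offset != 0:
        category = "nontemplated_3p" if three_nontemplated else "templated_3p"
    else:
        category = "reference"

    seed_affected = five_offset != 0 or any(
        SEED_START <= p <= SEED_END for p in substitutions
    )
    return IsomirCall(
        category=category,
        five_prime_offset=five_offset,
        three_prime_offset=three_offset,
        substitutions=frozenset(substitutions),
        seed_affected=seed_affected,
    )


def dominant_form(
    stack: ReadStack, mature: MatureForm, precursor_seq: str
) -> tuple[IsomirCall, str]:
    """Most abundant variant of a mature across libraries.

    Reads are grouped by (start, sequence); the group with the highest
    summed count wins.  Ties go to the reference form first, then to the
    lexicographically smallest sequence.
    """
    groups: dict[tuple[int, str], int] = {}
    for read in stack.reads:
        if read.end <= mature.offset or read.start >= mature.end:
            continue
        groups[(read.start, read.sequence)] = (
            groups.get((read.start, read.sequence), 0) + read.count
        )
    if not groups:
        raise NoDataError(
            f"no reads overlap the {mature.arm} mature of {stack.precursor_id}"
        )

    def rank(item):
        (start, seq), count = item
        is_reference = start == mature.offset and seq == mature.ref_sequence
        return (-count, not is_reference, seq)

    (start, seq), _ = min(groups.items(), key=rank)
    probe = AlignedRead(sequence=seq, count=1, library="_", start=start,
                        mismatches=_infer_mismatches(seq, start, precursor_seq))
    return classify_read(probe, mature, precursor_seq), seq


def _infer_mismatches(
    seq: str, start: int, precursor_seq: str
) -> frozenset[tuple[int, str]]:
    """Recompute mismatch annotations of a read by direct comparison."""
    mismatches = []
    for i, base in enumerate(seq):
        pos = start + i
        if 0 <= pos < len(precursor_seq):
            if precursor_seq[pos] != base:
                mismatches.append((i + 1, base))
    return frozenset(mismatches)


@dataclass
class IsomirDistribution:
    """Per-library and pooled category fractions, count-weighted."""

    per_library: dict[str, dict[str, float]] = field(default_factory=dict)
    pooled: dict[str, float] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        for lib, fracs in self.per_library.items():
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"fractions for {lib} do not sum to 1")


def summarize_isomirs(
    stacks: Mapping[str, ReadStack],
    precursors: Sequence[Precursor],
) -> IsomirDistribution:
    """Count-weighted isomiR category distribution per library and pooled.

    Every read is classified against the mature form(s) of its precursor;
    a read overlapping both matures is assigned to the one it overlaps
    most.  Non-overlapping (star/loop) reads are tallied in ``unassigned``.
    """
    by_id = {p.id: p for p in precursors}
    counts: dict[str, dict[str, int]] = {}
    unassigned: dict[str, int] = {}
    for pid, stack in stacks.items():
        precursor = by_id.get(pid)
        if precursor is None:
            continue
        for read in stack.reads:
            best, best_overlap = None, 0
            for m in precursor.matures:
                overlap = min(read.end, m.end) - max(read.start, m.offset)
                if overlap > best_overlap:
                    best, best_overlap = m, overlap
            if best is None:
                unassigned[read.library] = (
                    unassigned.get(read.library, 0) + read.count
                )
                continue
            call = classify_read(read, best, precursor.sequence)
            lib_counts = counts.setdefault(
                read.library, dict.fromkeys(CATEGORIES, 0)
            )
            lib_counts[call.category] += read.count

    dist = IsomirDistribution(counts=counts, unassigned=unassigned)
    pooled_totals = dict.fromkeys(CATEGORIES, 0)
    for lib, lib_counts in counts.items():
        total = sum(lib_counts.values())
        dist.per_library[lib] = {
            cat: (n / total if total else 0.0) for cat, n in lib_counts.items()
        }
        for cat, n in lib_counts.items():
            pooled_totals[cat] += n
    grand = sum(pooled_totals.values())
    if grand:
        dist.pooled = {cat: n / grand for cat, n in pooled_totals.items()}
    return dist
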