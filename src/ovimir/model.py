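"""Domain model for small-RNA hairpin characterization.

The objects here mirror the entities of a miRNA discovery experiment: a
:class:`Precursor` is a candidate stem-loop hairpin with genomic coordinates
and up to two mature products (one per arm), a :class:`ReadStack` holds the
sequencing reads aligned to one hairpin (the substrate for isomiR
classification), and a :class:`HomologyHit` records one similarity match
against an external database, used for conservation tiering and repeat
screening.

Coordinates are 0-based half-open throughout.  Nucleotide sequences are
stored uppercase in RNA form (``T`` is accepted on input and converted to
``U``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "NoDataError",
    "canonical_rna",
    "GenomicInterval",
    "MatureForm",
    "Precursor",
    "AlignedRead",
    "ReadStack",
    "HomologyHit",
    "HOMOLOGY_DBS",
    "total_count",
]


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not match the expected schema."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete analysis configuration."""


class NoDataError(ValueError):
    """An operation received no usable data."""


_RNA_RE = re.compile(r"^[ACGUN]+$")


def canonical_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U.

    Raises :class:`ValidationError` on characters outside A/C/G/U/T/N.
    """
    s = seq.strip().upper().replace("T", "U")
    if not s or not _RNA_RE.match(s):
        raise ValidationError(f"not a nucleotide sequence: {seq!r}")
    return s


STRANDS = ("+", "-")
ARMS = ("5p", "3p")
HOMOLOGY_DBS = ("mirbase", "genome_self", "rfam_refseq")

# Mature-length window admitted by the read preprocessing.
MATURE_MIN_LEN = 15
MATURE_MAX_LEN = 32


def total_count(counts: Mapping[str, int]) -> int:
    """Total reads over all libraries; a 'total' is always derived, never stored."""
    return sum(counts.values())


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _check_counts(counts: Mapping[str, int]) -> dict[str, int]:
    out = {}
    for lib, n in counts.items():
        if not lib:
            raise ValidationError("empty library label")
        if int(n) != n or n < 0:
            raise ValidationError(f"negative or non-integer count {n!r} for {lib}")
        out[str(lib)] = int(n)
    return out


@dataclass
class MatureForm:
    """One mature miRNA product excised from a hairpin arm.

    ``offset`` locates the mature within the precursor sequence (0-based).
    ``counts`` maps library label to read count; an absent label means zero.
    """

    arm: str
    ref_sequence: str
    offset: int
    counts: dict[str, int] = field(default_factory=dict)
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"invalid arm {self.arm!r}")
        self.ref_sequence = canonical_rna(self.ref_sequence)
        if not (MATURE_MIN_LEN <= len(self.ref_sequence) <= MATURE_MAX_LEN):
            raise ValidationError(
                f"mature length {len(self.ref_sequence)} outside "
                f"[{MATURE_MIN_LEN}, {MATURE_MAX_LEN}]"
            )
        if self.offset < 0:
            raise ValidationError(f"negative mature offset {self.offset}")
        self.counts = _check_counts(self.counts)

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)

    @property
    def end(self) -> int:
        return self.offset + len(self.ref_sequence)


@dataclass
class Precursor:
    """A candidate miRNA hairpin with its mature form(s)."""

    id: str
    interval: GenomicInterval
    sequence: str
    score: float
    is_known: bool = False
    mature_5p: Optional[MatureForm] = None
    mature_3p: Optional[MatureForm] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("empty precursor id")
        self.sequence = canonical_rna(self.sequence)
        if len(self.sequence) != len(self.interval):
            raise ValidationError(
                f"{self.id}: sequence length {len(self.sequence)} != interval "
                f"length {len(self.interval)}"
            )
        if self.mature_5p is None and self.mature_3p is None:
            raise ValidationError(f"{self.id}: no mature form attached")
        for m in self.matures:
            if m.end > len(self.sequence):
                raise ValidationError(
                    f"{self.id}: mature {m.arm} exceeds precursor bounds"
                )
            if self.sequence[m.offset : m.end] != m.ref_sequence:
                raise ValidationError(
                    f"{self.id}: mature {m.arm} sequence does not match "
                    "precursor at its offset"
                )

    @property
    def matures(self) -> list[MatureForm]:
        return [m for m in (self.mature_5p, self.mature_3p) if m is not None]

    def mature(self, arm: str) -> Optional[MatureForm]:
        if arm not in ARMS:
            raise ValidationError(f"invalid arm {arm!r}")
        return self.mature_5p if arm == "5p" else self.mature_3p

    def library_count(self, library: str) -> int:
        """Reads over all mature forms in one library."""
        return sum(m.count(library) for m in self.matures)


@dataclass(frozen=True)
class AlignedRead:
    """One (collapsed) read aligned to a precursor.

    ``start`` is the offset of read base 1 on the precursor; negative values
    denote an upstream overhang.  ``mismatches`` holds (1-based read
    position, read base) pairs where the read disagrees with the precursor.
    """

    sequence: str
    count: int
    library: str
    start: int
    mismatches: frozenset[tuple[int, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonical_rna(self.sequence))
        object.__setattr__(
            self,
            "mismatches",
            frozenset((int(p), canonical_rna(b)) for p, b in self.mismatches),
        )
        if self.count < 1:
            raise ValidationError(f"read count must be >= 1, got {self.count}")
        if not self.library:
            raise ValidationError("empty library label")
        for pos, base in self.mismatches:
            if not (1 <= pos <= len(self.sequence)):
                raise ValidationError(
                    f"mismatch position {pos} outside read of length "
                    f"{len(self.sequence)}"
                )
            if len(base) != 1:
                raise ValidationError(f"mismatch base must be one nucleotide: {base!r}")

    @property
    def end(self) -> int:
        """Exclusive end offset on the precursor."""
        return self.start + len(self.sequence)


@dataclass
class ReadStack:
    """All reads aligned to one precursor."""

    precursor_id: str
    reads: list[AlignedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.precursor_id:
            raise ValidationError("empty precursor id")

    def __len__(self) -> int:
        return len(self.reads)

    def total(self) -> int:
        return sum(r.count for r in self.reads)


@dataclass(frozen=True)
class HomologyHit:
    """One similarity match from a conservation / repeat screen."""

    query_id: str
    subject_id: str
    subject_species: str
    evalue: float
    db: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValidationError(f"E-value must be positive, got {self.evalue}")
        if self.db not in HOMOLOGY_DBS:
            raise ValidationError(
                f"unknown hit database {self.db!r}; expected one of {HOMOLOGY_DBS}"
            )


def check_chrom_lengths(lengths: Mapping[str, int]) -> dict[str, int]:
    """Validate a chromosome-length table (all lengths positive)."""
    out = {}
    for chrom, n in lengths.items():
        if not chrom:
            raise ValidationError("empty chromosome name in length table")
        if n <= 0:
            raise ValidationError(f"chromosome {chrom} has non-positive length {n}")
        out[str(chrom)] = int(n)
    return out
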