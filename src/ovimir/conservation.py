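"""Conservation tiering and deterministic nomenclature.

Candidates are tiered by how widely their hairpin is conserved, judged from
miRBase similarity hits at three E-value thresholds: broadly conserved
(significant match in at least 5 other species, E < 4e-09), narrowly
conserved (2-4 species, E < 9e-05), conserved in a single species
(E < 2e-04; this bucket holds, e.g., single-species family matches and
distant homologs), or non-conserved (species-specific).

Naming follows miRBase conventions for a new species prefix (here ``oar``):
conserved candidates inherit the name of their closest-matching homolog
mature, with the seed region (positions 2-8) weighted double in the
similarity score; highly similar candidates mapping to the same name get
progressive letters (``...la``, ``...lb``) in genomic-coordinate order;
distinct precursors encoding an identical mature share a number with ``-1``
/ ``-2`` suffixes; non-conserved candidates get provisional names
``oar-miR-N1`` onward in coordinate order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    ConfigurationError,
    HomologyHit,
    Precursor,
    ValidationError,
    total_count,
)

__all__ = [
    "ConservationCall",
    "TIERS",
    "assign_tier",
    "similarity_score",
    "assign_names",
    "group_families",
    "family_of",
]

TIERS = ("conserved_broad", "conserved_narrow", "conserved_single", "nonconserved")

SEED_START = 2  # 1-based, inclusive
SEED_END = 8


@dataclass
class ConservationCall:
    precursor_id: str
    tier: str
    supporting_species: frozenset[str] = frozenset()
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"unknown conservation tier {self.tier!r}")
        self.supporting_species = frozenset(self.supporting_species)
        if self.tier == "conserved_broad" and len(self.supporting_species) < 5:
            raise ValidationError("broadly conserved call needs >= 5 species")
        if self.tier == "nonconserved" and self.supporting_species:
            raise ValidationError("non-conserved call cannot list species")


def assign_tier(
    precursor_id: str,
    hits: Iterable[HomologyHit],
    *,
    broad_e: float = 4e-09,
    narrow_e: float = 9e-05,
    single_e: float = 2e-04,
) -> ConservationCall:
    """Tier one candidate from its miRBase hits.

    Hits against other databases are ignored.  An empty hit list is valid
    and yields ``nonconserved``.
    """
    best: dict[str, float] = {}
    for h in hits:
        if h.db != "mirbase" or h.query_id != precursor_id:
            continue
        sp = h.subject_species
        if sp not in best or h.evalue < best[sp]:
            best[sp] = h.evalue

    broad_sp = frozenset(sp for sp, e in best.items() if e < broad_e)
    if len(broad_sp) >= 5:
        return ConservationCall(precursor_id, "conserved_broad", broad_sp)
    narrow_sp = frozenset(sp for sp, e in best.items() if e < narrow_e)
    if 1 < len(narrow_sp) < 5:
        return ConservationCall(precursor_id, "conserved_narrow", narrow_sp)
    single_sp = frozenset(sp for sp, e in best.items() if e < single_e)
    if len(single_sp) == 1:
        return ConservationCall(precursor_id, "conserved_single", single_sp)
    return ConservationCall(precursor_id, "nonconserved")


def similarity_score(query: str, subject: str) -> int:
    """Seed-weighted ungapped similarity between two mature sequences.

    The subject is slid over the query at every offset; the best offset's
    score is returned, counting 2 per matching base in the query seed
    (positions 2-8) and 1 per matching base elsewhere.
    """
    best = 0
    for offset in range(-(len(subject) - 1), len(query)):
        score = 0
        for qi in range(len(query)):
            si = qi - offset
            if 0 <= si < len(subject) and query[qi] == subject[si]:
                score += 2 if SEED_START <= qi + 1 <= SEED_END else 1
        best = max(best, score)
    return best


_SPECIES_PREFIX_RE = re.compile(r"^[a-z]{2,4}-")


def strip_species_prefix(name: str) -> str:
    return _SPECIES_PREFIX_RE.sub("", name)


def _representative_mature(precursor: Precursor):
    """Dominant mature form (highest total count; 5p on ties)."""
    return max(
        precursor.matures,
        key=lambda m: (total_count(m.counts), m.arm == "5p"),
    )


def _coord_key(p: Precursor) -> tuple:
    return (p.interval.chrom, p.interval.start, p.interval.end, p.id)


def assign_names(
    precursors: Sequence[Precursor],
    calls: Mapping[str, ConservationCall],
    homolog_catalog: Mapping[str, str],
    existing_names: Iterable[str] = (),
    *,
    species_prefix: str = "oar",
) -> dict[str, str]:
    """Assign one deterministic name per precursor.

    ``homolog_catalog`` maps homolog mature names (with their own species
    prefixes, e.g. ``bta-miR-2285l``) to sequences.  ``existing_names`` are
    catalog names already taken (known miRNAs of the target species).
    Returns {precursor id -> name}; names are unique within the run and
    independent of input order.
    """
    for p in precursors:
        if p.id not in calls:
            raise ConfigurationError(f"no conservation call for {p.id}")

    conserved = [p for p in precursors if calls[p.id].tier != "nonconserved"]
    nonconserved = [p for p in precursors if calls[p.id].tier == "nonconserved"]
    if conserved and not homolog_catalog:
        raise ConfigurationError(
            "conserved candidates present but the homolog catalog is empty"
        )

    taken = {strip_species_prefix(n) for n in existing_names}
    names: dict[str, str] = {}

    # --- conserved: closest-matching homolog mature, seed-weighted -------
    by_base: dict[str, list[Precursor]] = {}
    for p in sorted(conserved, key=_coord_key):
        query = _representative_mature(p).ref_sequence
        best_name = max(
            sorted(homolog_catalog),  # sorted for deterministic tie-break
            key=lambda n: similarity_score(query, homolog_catalog[n]),
        )
        by_base.setdefault(strip_species_prefix(best_name), []).append(p)

    for base, members in sorted(by_base.items()):
        if len(members) == 1 and base not in taken:
            names[members[0].id] = f"{species_prefix}-{base}"
            continue
        # Cluster members by identical encoded mature: identical matures
        # share the base name with -1/-2; distinct sequences get letters.
        seq_groups: dict[str, list[Precursor]] = {}
        for p in members:
            seq_groups.setdefault(_representative_mature(p).ref_sequence, []).append(p)
        groups = sorted(seq_groups.values(), key=lambda g: _coord_key(g[0]))
        need_letters = len(groups) > 1 or base in taken
        for gi, group in enumerate(groups):
            suffix = chr(ord("a") + gi) if need_letters else ""
            for mi, p in enumerate(sorted(group, key=_coord_key)):
                dup = f"-{mi + 1}" if len(group) > 1 else ""
                names[p.id] = f"{species_prefix}-{base}{suffix}{dup}"

    # --- non-conserved: provisional N-numbers in coordinate order --------
    # Precursors encoding an identical mature share one number.
    seq_to_group: dict[str, int] = {}
    groups_nc: list[list[Precursor]] = []
    for p in sorted(nonconserved, key=_coord_key):
        key_seqs = [m.ref_sequence for m in p.matures]
        gid = next((seq_to_group[s] for s in key_seqs if s in seq_to_group), None)
        if gid is None:
            gid = len(groups_nc)
            groups_nc.append([])
        groups_nc[gid].append(p)
        for s in key_seqs:
            seq_to_group[s] = gid
    for k, group in enumerate(groups_nc, start=1):
        base = f"{species_prefix}-miR-N{k}"
        if len(group) == 1:
            names[group[0].id] = base
        else:
            for mi, p in enumerate(sorted(group, key=_coord_key)):
                names[p.id] = f"{base}-{mi + 1}"

    values = list(names.values())
    if len(set(values)) != len(values):
        dupes = sorted({n for n in values if values.count(n) > 1})
        raise ValidationError(f"name collision(s) not resolved: {dupes}")
    return names


_ARM_SUFFIX_RE = re.compile(r"-(5p|3p)$")
# A duplicate-precursor index ("-1", "-2") is stripped only when the
# remainder still ends in the family number (with optional variant
# letters); otherwise the trailing digits ARE the family number.
_DUP_SUFFIX_RE = re.compile(r"^(.*\d[a-z]*)-\d+$")
_TRAILING_LETTERS_RE = re.compile(r"(?<=\d)[a-z]+$")


def family_of(name: str) -> str:
    """Family label: name stripped of species prefix, arm suffix, duplicate
    index, and trailing variant letters (``oar-miR-2285la`` -> ``miR-2285``)."""
    base = strip_species_prefix(name)
    base = _ARM_SUFFIX_RE.sub("", base)
    m = _DUP_SUFFIX_RE.match(base)
    if m:
        base = m.group(1)
    base = _TRAILING_LETTERS_RE.sub("", base)
    return base


def group_families(names: Mapping[str, str]) -> dict[str, list[str]]:
    """Partition named items into families; {family label -> sorted ids}."""
    out: dict[str, list[str]] = {}
    for item_id in sorted(names):
        out.setdefault(family_of(names[item_id]), []).append(item_id)
    return out
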