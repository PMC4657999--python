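"""Arm preference and same-mature grouping.

Both hairpin arms can yield functional mature products, and the dominant
arm can differ between tissues ("arm switching").  An arm counts as
expressed in a library when its mature reaches the read-count floor there;
the dominant arm is the one with the strictly greater count (ties go to 5p,
reflecting the genome-wide 5p majority; the tie-break is arbitrary and
documented as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import ConfigurationError, Precursor, ValidationError

__all__ = ["ArmProfile", "arm_profile", "count_arm_switches", "group_same_mature"]


@dataclass
class ArmProfile:
    """Per-library expressed arms and dominance for one precursor."""

    precursor_id: str
    expressed_arms: dict[str, frozenset[str]] = field(default_factory=dict)
    dominant_arm: dict[str, Optional[str]] = field(default_factory=dict)
    switch_flag: bool = False

    def __post_init__(self) -> None:
        for lib, arm in self.dominant_arm.items():
            if arm is not None and arm not in self.expressed_arms.get(
                lib, frozenset()
            ):
                raise ValidationError(
                    f"{self.precursor_id}: dominant arm {arm} not expressed in {lib}"
                )


def arm_profile(
    precursor: Precursor,
    libraries: Sequence[str],
    min_count: int = 10,
    *,
    strict_greater: bool = False,
) -> ArmProfile:
    """Expressed arms, per-library dominant arm, and the switch flag.

    An arm is expressed when its count reaches ``min_count`` (or strictly
    exceeds it with ``strict_greater``).  The switch flag is set when both
    libraries of the (ordered) pair have a dominant arm and they differ.
    """
    if len(libraries) < 1:
        raise ConfigurationError("at least one library label required")
    expressed: dict[str, frozenset[str]] = {}
    dominant: dict[str, Optional[str]] = {}
    for lib in libraries:
        arms = set()
        counts = {}
        for m in precursor.matures:
            c = m.count(lib)
            counts[m.arm] = c
            if (c > min_count) if strict_greater else (c >= min_count):
                arms.add(m.arm)
        expressed[lib] = frozenset(arms)
        if not arms:
            dominant[lib] = None
        elif len(arms) == 1:
            dominant[lib] = next(iter(arms))
        else:
            c5, c3 = counts.get("5p", 0), counts.get("3p", 0)
            dominant[lib] = "3p" if c3 > c5 else "5p"  # tie goes to 5p

    switch = False
    if len(libraries) >= 2:
        a, b = dominant.get(libraries[0]), dominant.get(libraries[1])
        switch = a is not None and b is not None and a != b
    return ArmProfile(
        precursor_id=precursor.id,
        expressed_arms=expressed,
        dominant_arm=dominant,
        switch_flag=switch,
    )


def count_arm_switches(profiles: Iterable[ArmProfile]) -> int:
    return sum(1 for p in profiles if p.switch_flag)


def group_same_mature(precursors: Iterable[Precursor]) -> dict[str, list[str]]:
    """Group precursors by exact (canonicalized) mature sequence.

    Returns {mature sequence -> sorted precursor ids}; a precursor with two
    matures appears under both sequences.  The result is a partition of the
    distinct mature sequences and is independent of input order.
    """
    groups: dict[str, set[str]] = {}
    for p in precursors:
        for m in p.matures:
            groups.setdefault(m.ref_sequence, set()).add(p.id)
    return {seq: sorted(ids) for seq, ids in groups.items()}


def duplicate_groups(precursors: Iterable[Precursor]) -> dict[str, list[str]]:
    """Only the same-mature groups with two or more distinct precursors."""
    return {
        seq: ids
        for seq, ids in group_same_mature(precursors).items()
        if len(ids) >= 2
    }
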