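"""Ground-truthed synthetic data for the whole characterization pipeline.

The generator emulates the data structure of a two-library small-RNA
discovery experiment on hairpin precursors: candidate hairpins placed on
synthetic chromosomes (with planted same-strand clusters), per-library
mature read counts honoring configured specificity quotas and arm-dominance
weights, per-read isomiR categories drawn from a configured multinomial and
realized by forward-editing the reference mature (templated edits copy
hairpin bases, non-templated additions draw from a weighted alphabet,
polymorphic reads substitute one internal base), homology-hit tables with
controllable conservation-tier quotas and E-value ranges, plus a
signal-to-noise table for score-cutoff selection and a handful of doomed
candidates exercising every drop rule.

Because reads are forward-edited rather than re-aligned, the mismatch
annotations in the emitted read-stack table are exact by construction, and
every read's true category is recorded in the ground-truth manifest.
Hairpins are random sequence with the star arm reverse-complement-biased to
the mature arm; no secondary-structure prediction is attempted.

Default parameter values reproduce the study conditions this package
characterizes: specificity quotas 12/76/84 (19/115/130 mature forms),
conservation-tier quotas 112/10/29/21, 13 duplicate-mature pairs, 7 planted
novel clusters holding 17 precursors, 5 arm switches, a 5p-dominance rate
of 0.64, isomiR category proportions near the observed pooled distribution
(reference 0.575), ~91% of mature lengths in the 18-24 nt band, and a
signal-to-noise table whose lowest admissible cutoff is 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as ovio
from .model import (
    ConfigurationError,
    GenomicInterval,
    HomologyHit,
    MatureForm,
    Precursor,
    AlignedRead,
    ReadStack,
)

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate"]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_BASES = np.array(list("ACGU"))

ISOMIR_CATEGORIES = (
    "reference",
    "templated_5p",
    "nontemplated_5p",
    "templated_3p",
    "nontemplated_3p",
    "both_ends_templated",
    "both_ends_nontemplated",
    "polymorphic",
)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_isomir_proportions() -> dict[str, float]:
    # Near the observed pooled distribution; the three rare classes share
    # the remaining 0.5%.
    return {
        "reference": 0.575,
        "templated_3p": 0.18,
        "nontemplated_3p": 0.105,
        "polymorphic": 0.085,
        "templated_5p": 0.05,
        "nontemplated_5p": 0.002,
        "both_ends_templated": 0.002,
        "both_ends_nontemplated": 0.001,
    }


def _default_snr_rows() -> tuple[tuple[float, float], ...]:
    return (
        (1, 2.1),
        (2, 3.4),
        (3, 5.0),
        (4, 8.2),
        (5, 37.0),
        (6, 41.0),
        (7, 52.0),
        (8, 60.0),
    )


@dataclass
class SimConfig:
    """Scenario parameters; defaults are the study conditions (see module
    docstring)."""

    seed: int = 0
    libraries: tuple[str, str] = ("LV", "GL")
    n_chromosomes: int = 27
    chrom_length_base: int = 2_500_000
    chrom_length_step: int = 91_000
    # (A_only, B_only, both) novel precursors, and how many of each class
    # carry two mature forms.
    specificity_quotas: tuple[int, int, int] = (12, 76, 84)
    two_mature_quotas: tuple[int, int, int] = (7, 39, 46)
    # (conserved_broad, conserved_narrow, conserved_single, nonconserved)
    tier_quotas: tuple[int, int, int, int] = (112, 10, 29, 21)
    duplicate_pairs: int = 13
    shared_homolog_pairs: int = 2
    cluster_sizes: tuple[int, ...] = (3, 3, 3, 2, 2, 2, 2)
    known_count: int = 20
    known_cluster_sizes: tuple[int, ...] = (3,)
    arm_switches: int = 5
    p_5p_dominant: float = 0.64
    # Read-depth model: counts are lognormal, floored at min_expressed_count
    # in libraries where the mature is present.
    min_expressed_count: int = 12
    log_mean: float = 4.3
    log_sigma: float = 0.9
    dominance_ratio: tuple[float, float] = (1.6, 4.0)
    isomir_proportions: dict[str, float] = field(
        default_factory=_default_isomir_proportions
    )
    nontemplated_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.45, "U": 0.35, "C": 0.10, "G": 0.10}
    )
    inband_length_prob: float = 0.9093
    inband_lengths: tuple[int, ...] = (20, 21, 22)
    outband_lengths: tuple[int, ...] = (15, 16, 26, 27)
    star_read_fraction: float = 0.03
    cluster_gap_range: tuple[int, int] = (500, 9_000)
    spacer_range: tuple[int, int] = (15_000, 40_000)
    snr_rows: tuple[tuple[float, float], ...] = field(default_factory=_default_snr_rows)
    score_range: tuple[float, float] = (5.1, 90.0)
    # Doomed candidates exercising each drop rule.
    n_low_score: int = 3
    n_low_count: int = 3
    n_repeat: int = 4
    n_other_ncrna: int = 6
    species_pool: tuple[str, ...] = (
        "bta", "hsa", "mmu", "ssc", "chi", "eca", "cfa", "rno", "oan", "gga",
    )

    def validate(self) -> None:
        if abs(sum(self.isomir_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("isomiR proportions must sum to 1")
        if set(self.isomir_proportions) != set(ISOMIR_CATEGORIES):
            raise ConfigurationError("isomiR proportions must cover all categories")
        n_novel = sum(self.specificity_quotas)
        if sum(self.tier_quotas) != n_novel:
            raise ConfigurationError(
                "tier quotas must sum to the novel precursor count"
            )
        for q2, q in zip(self.two_mature_quotas, self.specificity_quotas):
            if q2 > q:
                raise ConfigurationError("two-mature quota exceeds class quota")
        n_single_b = self.specificity_quotas[1] - self.two_mature_quotas[1]
        if 2 * self.duplicate_pairs > n_single_b:
            raise ConfigurationError(
                "not enough single-mature B-only precursors for duplicate pairs"
            )
        if sum(self.cluster_sizes) > n_novel:
            raise ConfigurationError("cluster members exceed precursor count")
        if self.arm_switches > self.two_mature_quotas[2]:
            raise ConfigurationError(
                "arm switches need two-mature precursors present in both libraries"
            )
        if self.tier_quotas[3] < 2:
            raise ConfigurationError(
                "need at least 2 nonconserved precursors (one duplicate pair)"
            )
        if sum(self.known_cluster_sizes) > self.known_count:
            raise ConfigurationError("known cluster members exceed known count")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by precursor id."""

    score_cutoff: float
    specificity: dict[str, str] = field(default_factory=dict)
    tier: dict[str, str] = field(default_factory=dict)
    dominant_arm: dict[str, dict[str, str]] = field(default_factory=dict)
    arm_switch_ids: list[str] = field(default_factory=list)
    duplicate_pairs: list[list[str]] = field(default_factory=list)
    novel_clusters: list[list[str]] = field(default_factory=list)
    known_clusters: list[list[str]] = field(default_factory=list)
    drop_reasons: dict[str, str] = field(default_factory=dict)
    # Parallel to the emitted stack row order per precursor; star reads are
    # labelled "star".
    read_categories: dict[str, list[str]] = field(default_factory=dict)
    isomir_proportions: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    precursors: list[Precursor]
    stacks: dict[str, ReadStack]
    hits: list[HomologyHit]
    homolog_catalog: dict[str, str]
    chrom_lengths: dict[str, int]
    snr_rows: list[tuple[float, float]]
    truth: GroundTruth

    def kept_novel(self) -> list[Precursor]:
        return [
            p
            for p in self.precursors
            if not p.is_known and p.id not in self.truth.drop_reasons
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every canonical file; returns {artifact name -> path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "precursors": outdir / "precursors.tsv",
            "read_stacks": outdir / "read_stacks.tsv",
            "homology": outdir / "homology.tsv",
            "chrom_lengths": outdir / "chrom_lengths.tsv",
            "snr": outdir / "snr.tsv",
            "hairpins": outdir / "hairpins.fasta",
            "homolog_matures": outdir / "homolog_matures.fasta",
            "truth": outdir / "truth.json",
        }
        ovio.write_precursor_table(
            self.precursors, paths["precursors"], libraries=self.config.libraries
        )
        ovio.write_read_stacks(self.stacks, paths["read_stacks"])
        ovio.write_homology_hits(self.hits, paths["homology"])
        ovio.write_chrom_lengths(self.chrom_lengths, paths["chrom_lengths"])
        ovio.write_snr_table(self.snr_rows, paths["snr"])
        ovio.write_fasta(
            {p.id: p.sequence for p in self.precursors}, paths["hairpins"]
        )
        ovio.write_fasta(self.homolog_catalog, paths["homolog_matures"])
        paths["truth"].write_text(self.truth.to_json())
        return paths


# ---------------------------------------------------------------------------
# roster bookkeeping


@dataclass
class _Spec:
    """Working record for one precursor before sequences exist."""

    id: str
    kind: str  # "novel" | "known" | doomed reason
    spec_class: Optional[str] = None  # A_only / B_only / both
    two_mature: bool = False
    mature_arm: str = "3p"  # arm of the single mature when not two_mature
    tier: Optional[str] = None
    dup_partner: Optional[str] = None
    shared_homolog_key: Optional[str] = None
    arm_switch: bool = False
    dominant: Optional[str] = None
    cluster_idx: Optional[int] = None  # planted cluster index (novel or known)
    # filled during count pre-draw / sequence construction
    out_band: bool = False
    counts_by_arm: dict[str, dict[str, int]] = field(default_factory=dict)
    dominant_by_lib: dict[str, str] = field(default_factory=dict)
    mature_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def arms(self) -> list[str]:
        return ["5p", "3p"] if self.two_mature else [self.mature_arm]

    def total_mass(self) -> int:
        return sum(
            n for arm in self.counts_by_arm.values() for n in arm.values()
        )


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int, avoid_seed: bool) -> str:
    """Substitute ``n_sub`` distinct positions (1-based seed 2-8 avoided on
    request so similarity-based matching stays unambiguous)."""
    positions = [
        i
        for i in range(len(seq))
        if not (avoid_seed and 1 <= i <= 7)  # 0-based 1..7 == positions 2..8
    ]
    chosen = rng.choice(len(positions), size=min(n_sub, len(positions)), replace=False)
    out = list(seq)
    for ci in np.sort(chosen):
        pos = positions[int(ci)]
        alternatives = [b for b in "ACGU" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _draw_length(rng: np.random.Generator, cfg: SimConfig, out_band: bool) -> int:
    if out_band:
        return int(rng.choice(cfg.outband_lengths))
    return int(rng.choice(cfg.inband_lengths))


def _draw_spec_counts(rng: np.random.Generator, s: _Spec, cfg: SimConfig) -> None:
    """Fill per-arm, per-library counts and the per-library dominant arm."""
    lib_a, _ = cfg.libraries
    present = {
        "A_only": (True, False),
        "B_only": (False, True),
        "both": (True, True),
    }[s.spec_class]
    counts: dict[str, dict[str, int]] = {"5p": {}, "3p": {}}
    for lib, here in zip(cfg.libraries, present):
        if not here:
            continue
        if s.kind == "low_count":
            counts[s.arms[0]][lib] = int(rng.integers(2, 5))
            s.dominant_by_lib[lib] = s.arms[0]
        elif s.two_mature:
            dom = ("5p" if lib == lib_a else "3p") if s.arm_switch else s.dominant
            minor = _draw_count(rng, cfg)
            major = int(minor * rng.uniform(*cfg.dominance_ratio)) + 1
            counts[dom][lib] = major
            counts["3p" if dom == "5p" else "5p"][lib] = minor
            s.dominant_by_lib[lib] = dom
        else:
            counts[s.arms[0]][lib] = _draw_count(rng, cfg)
            s.dominant_by_lib[lib] = s.arms[0]
    s.counts_by_arm = counts


def _draw_count(rng: np.random.Generator, cfg: SimConfig) -> int:
    return max(cfg.min_expressed_count, int(rng.lognormal(cfg.log_mean, cfg.log_sigma)))


def _weighted_base(rng: np.random.Generator, weights: dict[str, float],
                   exclude: str | None = None) -> str:
    items = [(b, w) for b, w in sorted(weights.items()) if b != exclude]
    total = sum(w for _, w in items)
    r = rng.random() * total
    acc = 0.0
    for b, w in items:
        acc += w
        if r <= acc:
            return b
    return items[-1][0]


# ---------------------------------------------------------------------------
# read construction: forward-edit the reference mature


def _make_variant(
    rng: np.random.Generator,
    category: str,
    mature: MatureForm,
    hairpin: str,
    cfg: SimConfig,
) -> tuple[int, str, frozenset[tuple[int, str]]]:
    m0, m1 = mature.offset, mature.end
    seq = mature.ref_sequence

    def nt_base(templated: str) -> str:
        return _weighted_base(rng, cfg.nontemplated_weights, exclude=templated)

    if category == "reference":
        return m0, seq, frozenset()
    if category == "templated_5p":
        if rng.random() < 0.5:
            return m0 - 1, hairpin[m0 - 1] + seq, frozenset()
        return m0 + 1, seq[1:], frozenset()
    if category == "nontemplated_5p":
        b = nt_base(hairpin[m0 - 1])
        return m0 - 1, b + seq, frozenset({(1, b)})
    if category == "templated_3p":
        d = int(rng.choice([-2, -1, 1, 2]))
        if d > 0:
            return m0, seq + hairpin[m1 : m1 + d], frozenset()
        return m0, seq[:d], frozenset()
    if category == "nontemplated_3p":
        b = nt_base(hairpin[m1])
        return m0, seq + b, frozenset({(len(seq) + 1, b)})
    if category == "both_ends_templated":
        five_ext = rng.random() < 0.5
        three_ext = rng.random() < 0.5
        start = m0 - 1 if five_ext else m0 + 1
        core = hairpin[m0 - 1] + seq if five_ext else seq[1:]
        core = core + hairpin[m1] if three_ext else core[:-1]
        return start, core, frozenset()
    if category == "both_ends_nontemplated":
        # templated 5' shift plus a non-templated 3' addition
        five_ext = rng.random() < 0.5
        start = m0 - 1 if five_ext else m0 + 1
        core = hairpin[m0 - 1] + seq if five_ext else seq[1:]
        b = nt_base(hairpin[m1])
        return start, core + b, frozenset({(len(core) + 1, b)})
    if category == "polymorphic":
        pos = int(rng.integers(1, len(seq) + 1))  # 1-based mature position
        alternatives = [x for x in "ACGU" if x != seq[pos - 1]]
        b = alternatives[int(rng.integers(3))]
        return m0, seq[: pos - 1] + b + seq[pos:], frozenset({(pos, b)})
    raise ConfigurationError(f"unknown isomiR category {category!r}")


# ---------------------------------------------------------------------------
# main generator


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate one fully ground-truthed scenario (deterministic per seed)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib_a, lib_b = cfg.libraries

    chrom_names = [str(i) for i in range(1, cfg.n_chromosomes)] + ["X"]
    chrom_lengths = {
        name: cfg.chrom_length_base + cfg.chrom_length_step * i
        for i, name in enumerate(chrom_names)
    }

    truth = GroundTruth(
        score_cutoff=float(
            min(c for c, s in cfg.snr_rows if s > 10.0)
        ),
        isomir_proportions=dict(cfg.isomir_proportions),
    )

    # --- roster -----------------------------------------------------------
    specs: list[_Spec] = []
    class_labels = ("A_only", "B_only", "both")
    idx = 0
    for cls, quota, two_q in zip(
        class_labels, cfg.specificity_quotas, cfg.two_mature_quotas
    ):
        for j in range(quota):
            idx += 1
            specs.append(
                _Spec(
                    id=f"nov-{idx:03d}",
                    kind="novel",
                    spec_class=cls,
                    two_mature=j < two_q,
                )
            )

    # Duplicate-mature pairs: single-mature B-only precursors, paired.
    b_singles = [
        s for s in specs if s.spec_class == "B_only" and not s.two_mature
    ]
    for k in range(cfg.duplicate_pairs):
        a, b = b_singles[2 * k], b_singles[2 * k + 1]
        a.dup_partner, b.dup_partner = b.id, a.id
        truth.duplicate_pairs.append(sorted([a.id, b.id]))

    # Conservation tiers: the first duplicate pair is forced nonconserved
    # (exercising provisional-name -1/-2 suffixes); the rest of the
    # nonconserved quota is drawn from non-duplicate precursors.
    pair0 = set(truth.duplicate_pairs[0])
    nondup = [s for s in specs if s.dup_partner is None]
    order = rng.permutation(len(nondup))
    n_nc_rest = cfg.tier_quotas[3] - 2
    nonconserved_ids = pair0 | {nondup[int(i)].id for i in order[:n_nc_rest]}
    remaining = [s for s in specs if s.id not in nonconserved_ids]
    order2 = rng.permutation(len(remaining))
    tier_of: dict[str, str] = {pid: "nonconserved" for pid in nonconserved_ids}
    cursor = 0
    for tier, quota in zip(
        ("conserved_broad", "conserved_narrow", "conserved_single"),
        cfg.tier_quotas[:3],
    ):
        for _ in range(quota):
            tier_of[remaining[int(order2[cursor])].id] = tier
            cursor += 1
    for s in specs:
        s.tier = tier_of[s.id]
        truth.tier[s.id] = s.tier

    # Shared-homolog pairs (letter suffixes): conserved, non-duplicate,
    # single-mature precursors paired up.
    conserved_pool = [
        s
        for s in specs
        if s.tier != "nonconserved" and s.dup_partner is None and not s.two_mature
    ]
    shared_keys: dict[str, list[_Spec]] = {}
    for k in range(cfg.shared_homolog_pairs):
        a, b = conserved_pool[2 * k], conserved_pool[2 * k + 1]
        key = f"shared-{k}"
        a.shared_homolog_key = b.shared_homolog_key = key
        shared_keys[key] = [a, b]

    # Arm dominance and switches (switches need presence in both libraries
    # and two matures).
    both_two = [s for s in specs if s.spec_class == "both" and s.two_mature]
    for k, s in enumerate(both_two):
        if k < cfg.arm_switches:
            s.arm_switch = True
            truth.arm_switch_ids.append(s.id)
        else:
            s.dominant = "5p" if rng.random() < cfg.p_5p_dominant else "3p"
    for s in specs:
        if s.two_mature and s.dominant is None and not s.arm_switch:
            s.dominant = "5p" if rng.random() < cfg.p_5p_dominant else "3p"
        if not s.two_mature:
            s.mature_arm = "3p" if rng.random() < 0.5 else "5p"
            if s.dup_partner is not None:
                s.mature_arm = "3p"  # duplicate pairs share a 3p mature

    # Known precursors and doomed candidates.
    known_specs = [
        _Spec(id=f"kno-{i + 1:03d}", kind="known", spec_class="both",
              two_mature=i % 2 == 0)
        for i in range(cfg.known_count)
    ]
    for s in known_specs:
        if s.two_mature:
            s.dominant = "5p" if rng.random() < cfg.p_5p_dominant else "3p"
        else:
            s.mature_arm = "3p" if rng.random() < 0.5 else "5p"
    doomed_specs: list[_Spec] = []
    for reason, n in (
        ("low_score", cfg.n_low_score),
        ("low_count", cfg.n_low_count),
        ("repeat", cfg.n_repeat),
        ("other_ncrna", cfg.n_other_ncrna),
    ):
        for i in range(n):
            s = _Spec(
                id=f"bad-{reason}-{i + 1}", kind=reason, spec_class="both"
            )
            s.mature_arm = "3p"
            doomed_specs.append(s)
            truth.drop_reasons[s.id] = reason

    # --- cluster membership and genomic placement -------------------------
    novel_cluster_members: list[list[_Spec]] = []
    non_dup_free = [
        s for s in specs if s.dup_partner is None and s.shared_homolog_key is None
    ]
    ci = 0
    for size in cfg.cluster_sizes:
        members = non_dup_free[ci : ci + size]
        ci += size
        for m in members:
            m.cluster_idx = len(novel_cluster_members)
        novel_cluster_members.append(members)
        truth.novel_clusters.append(sorted(m.id for m in members))
    known_cluster_members: list[list[_Spec]] = []
    ki = 0
    for size in cfg.known_cluster_sizes:
        members = known_specs[ki : ki + size]
        ki += size
        known_cluster_members.append(members)
        truth.known_clusters.append(sorted(m.id for m in members))

    clustered = {s.id for group in novel_cluster_members for s in group}
    clustered |= {s.id for group in known_cluster_members for s in group}
    units: list[list[_Spec]] = list(novel_cluster_members) + list(
        known_cluster_members
    )
    units += [
        [s]
        for s in specs + known_specs + doomed_specs
        if s.id not in clustered
    ]

    # --- per-library counts (pre-drawn so read-length banding can be
    # stratified by read mass) ------------------------------------------
    all_specs = specs + known_specs + doomed_specs
    for s in all_specs:
        _draw_spec_counts(rng, s, cfg)

    # Mature lengths fall in the 18-24 nt band with the configured
    # probability *of read mass*: length-sharing groups (duplicate and
    # shared-homolog pairs share a sequence) are assigned out-of-band
    # status in shuffled order until the out-of-band read mass reaches the
    # configured share.  This realizes the read-level band rate with low
    # variance, as a read-length histogram of real libraries would show.
    length_groups: list[list[_Spec]] = []
    grouped_ids: set[str] = set()
    by_id_spec = {s.id: s for s in all_specs}
    for a_id, b_id in truth.duplicate_pairs:
        length_groups.append([by_id_spec[a_id], by_id_spec[b_id]])
        grouped_ids |= {a_id, b_id}
    for members in shared_keys.values():
        length_groups.append(list(members))
        grouped_ids |= {m.id for m in members}
    length_groups += [[s] for s in all_specs if s.id not in grouped_ids]
    total_mass = sum(s.total_mass() for s in all_specs)
    target_out = (1.0 - cfg.inband_length_prob) * total_mass
    acc = 0.0
    for gi in rng.permutation(len(length_groups)):
        group = length_groups[int(gi)]
        mass = sum(s.total_mass() for s in group)
        if acc + mass <= target_out * 1.1:
            for s in group:
                s.out_band = True
            acc += mass
        if acc >= target_out:
            break

    # --- sequences, counts, placement, reads ------------------------------
    precursors: list[Precursor] = []
    stacks: dict[str, ReadStack] = {}
    hits: list[HomologyHit] = []
    homolog_catalog: dict[str, str] = {}
    cat_names = list(ISOMIR_CATEGORIES)
    p_vec = np.array([cfg.isomir_proportions[c] for c in cat_names])

    dup_seq_cache: dict[str, str] = {}
    shared_seq_cache: dict[str, str] = {}
    homolog_idx = 0

    cursors = {name: 50_000 for name in chrom_names}
    unit_chrom = {i: chrom_names[i % len(chrom_names)] for i in range(len(units))}

    for ui, unit in enumerate(units):
        chrom = unit_chrom[ui]
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursors[chrom] + int(rng.integers(*cfg.spacer_range))
        for mi, s in enumerate(unit):
            if mi > 0:
                pos += int(rng.integers(*cfg.cluster_gap_range))

            # -- mature and hairpin sequences
            if s.dup_partner is not None and s.dup_partner in dup_seq_cache:
                primary = dup_seq_cache[s.dup_partner]
            elif s.shared_homolog_key in shared_seq_cache:
                primary = _mutate(
                    rng, shared_seq_cache[s.shared_homolog_key], 3, avoid_seed=True
                )
            else:
                primary = _rand_seq(rng, _draw_length(rng, cfg, s.out_band))
            if s.dup_partner is not None:
                dup_seq_cache[s.id] = primary
            if s.shared_homolog_key is not None and (
                s.shared_homolog_key not in shared_seq_cache
            ):
                shared_seq_cache[s.shared_homolog_key] = primary

            star = _mutate(rng, _revcomp(primary), 3, avoid_seed=False)
            if s.two_mature:
                seq_5p, seq_3p = (primary, star) if (
                    s.mature_arm != "3p" or s.dominant == "5p" or s.arm_switch
                ) else (star, primary)
            elif s.mature_arm == "5p":
                seq_5p, seq_3p = primary, star
            else:
                seq_5p, seq_3p = star, primary
            flank5 = _rand_seq(rng, 4)
            flank3 = _rand_seq(rng, 4)
            loop = _rand_seq(rng, int(rng.integers(8, 15)))
            hairpin = flank5 + seq_5p + loop + seq_3p + flank3
            off_5p = len(flank5)
            off_3p = len(flank5) + len(seq_5p) + len(loop)

            # -- per-library counts (pre-drawn)
            counts = s.counts_by_arm
            arms = s.arms
            present = {
                "A_only": (True, False),
                "B_only": (False, True),
                "both": (True, True),
            }[s.spec_class]
            if s.kind in ("novel", "known"):
                truth.dominant_arm[s.id] = s.dominant_by_lib
                if s.kind == "novel":
                    truth.specificity[s.id] = s.spec_class

            # -- score
            if s.kind == "low_score":
                score = float(rng.uniform(0.5, truth.score_cutoff - 0.5))
            else:
                score = float(rng.uniform(*cfg.score_range))

            mk = lambda arm, seq, off: MatureForm(
                arm=arm, ref_sequence=seq, offset=off,
                counts=counts[arm] if arm in arms else {},
            )
            mature_5p = mk("5p", seq_5p, off_5p) if "5p" in arms else None
            mature_3p = mk("3p", seq_3p, off_3p) if "3p" in arms else None
            interval = GenomicInterval(
                chrom=chrom, start=pos, end=pos + len(hairpin), strand=strand
            )
            precursor = Precursor(
                id=s.id,
                interval=interval,
                sequence=hairpin,
                score=score,
                is_known=s.kind == "known",
                mature_5p=mature_5p,
                mature_3p=mature_3p,
            )
            precursors.append(precursor)
            s.mature_seqs = {m.arm: m.ref_sequence for m in precursor.matures}
            pos = interval.end

            # -- reads
            stack = ReadStack(precursor_id=s.id)
            categories: list[str] = []
            for m in precursor.matures:
                for lib in cfg.libraries:
                    n = m.count(lib)
                    if n == 0:
                        continue
                    draws = rng.multinomial(n, p_vec)
                    for cat, k in zip(cat_names, draws):
                        if k == 0:
                            continue
                        start, seq, mm = _make_variant(
                            rng, cat, m, hairpin, cfg
                        )
                        stack.reads.append(
                            AlignedRead(
                                sequence=seq, count=int(k), library=lib,
                                start=start, mismatches=mm,
                            )
                        )
                        categories.append(cat)
            # star reads for single-mature precursors (excluded downstream)
            if not s.two_mature and s.kind != "low_count":
                star_arm = "5p" if s.mature_arm == "3p" else "3p"
                star_off = off_5p if star_arm == "5p" else off_3p
                star_seq = seq_5p if star_arm == "5p" else seq_3p
                for lib, here in zip(cfg.libraries, present):
                    if not here:
                        continue
                    k = rng.binomial(
                        precursor.library_count(lib), cfg.star_read_fraction
                    )
                    if k > 0:
                        stack.reads.append(
                            AlignedRead(
                                sequence=star_seq, count=int(k), library=lib,
                                start=star_off,
                            )
                        )
                        categories.append("star")
            stacks[s.id] = stack
            truth.read_categories[s.id] = categories

            # -- homology hits and homolog catalog
            if s.kind in ("novel",):
                hits.extend(
                    _tier_hits(rng, s, cfg)
                )
                if s.tier != "nonconserved":
                    if s.shared_homolog_key is not None:
                        key = s.shared_homolog_key
                        if f"_name:{key}" not in shared_seq_cache:
                            homolog_idx += 1
                            name = f"bta-miR-{2280 + homolog_idx}l"
                            shared_seq_cache[f"_name:{key}"] = name
                            homolog_catalog[name] = _mutate(
                                rng, shared_seq_cache[key], 2, avoid_seed=True
                            )
                    elif s.dup_partner is None or s.dup_partner not in {
                        p.id for p in precursors
                    }:
                        homolog_idx += 1
                        name = f"bta-miR-{2280 + homolog_idx}"
                        homolog_catalog[name] = _mutate(
                            rng, primary, 2, avoid_seed=True
                        )
            elif s.kind == "repeat":
                for j in range(6):
                    hits.append(
                        HomologyHit(
                            query_id=s.id,
                            subject_id=f"{chrom_names[j % 5]}:{100000 * (j + 1)}-"
                            f"{100000 * (j + 1) + 80}",
                            subject_species="oar",
                            evalue=1e-12,
                            db="genome_self",
                        )
                    )
            elif s.kind == "other_ncrna":
                hits.append(
                    HomologyHit(
                        query_id=s.id,
                        subject_id="U6-snRNA-like",
                        subject_species="oar",
                        evalue=1e-10,
                        db="rfam_refseq",
                    )
                )
        cursors[chrom] = pos
        if cursors[chrom] >= chrom_lengths[chrom] - 60_000:
            raise ConfigurationError(
                f"chromosome {chrom} too short for the configured layout"
            )

    return SimResult(
        config=cfg,
        precursors=precursors,
        stacks=stacks,
        hits=hits,
        homolog_catalog=homolog_catalog,
        chrom_lengths=chrom_lengths,
        snr_rows=list(cfg.snr_rows),
        truth=truth,
    )


def _tier_hits(
    rng: np.random.Generator, s: _Spec, cfg: SimConfig
) -> list[HomologyHit]:
    """miRBase hits realizing one conservation tier (plus benign extras)."""
    out: list[HomologyHit] = []

    def hit(species: str, evalue: float) -> HomologyHit:
        return HomologyHit(
            query_id=s.id,
            subject_id=f"{species}-mir-hit",
            subject_species=species,
            evalue=float(evalue),
            db="mirbase",
        )

    pool = list(cfg.species_pool)
    if s.tier == "conserved_broad":
        n_sp = int(rng.integers(5, 9))
        species = rng.choice(pool, size=n_sp, replace=False)
        for sp in species:
            out.append(hit(str(sp), 10 ** rng.uniform(-40, -9.5)))
    elif s.tier == "conserved_narrow":
        n_sp = int(rng.integers(2, 5))
        species = rng.choice(pool, size=n_sp, replace=False)
        for sp in species:
            out.append(hit(str(sp), 10 ** rng.uniform(-8, -4.2)))
    elif s.tier == "conserved_single":
        out.append(hit("bta", 10 ** rng.uniform(-20, -3.8)))
    else:  # nonconserved: only hopeless matches, if any
        if rng.random() < 0.5:
            out.append(hit("dme", 10 ** rng.uniform(-2, 0)))
    # benign self-genome hits (below the repeat count threshold)
    n_self = int(rng.integers(0, 3))
    for j in range(n_self):
        out.append(
            HomologyHit(
                query_id=s.id,
                subject_id=f"{int(rng.integers(1, 27))}:{int(rng.integers(1, 2_000_000))}-"
                f"{int(rng.integers(2_000_001, 2_100_000))}",
                subject_species="oar",
                evalue=1e-15,
                db="genome_self",
            )
        )
    return out
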