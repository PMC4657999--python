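"""Readers and writers for the canonical tab-separated dialects.

The discovery tooling this package post-processes emits a mix of HTML/CSV
reports that are impractical to parse; instead a canonical TSV dialect is
defined for each input:

* precursor table — columns ``id, chrom, start, end, strand, score,
  is_known, sequence, arm, mature_seq, mature_offset`` followed by one count
  column per library; one row per mature form, grouped by ``id``;
* read-stack table — ``precursor_id, library, start, sequence, count,
  mismatches`` with mismatches as semicolon-joined ``pos:base`` pairs
  (1-based read positions);
* homology-hit table — ``query_id, subject_id, subject_species, evalue, db``;
* chromosome-length table — ``chrom, length_bp``;
* signal-to-noise table — ``cutoff, snr``.

FASTA is read/written with Biopython.  BED output is BED6, 0-based
half-open, matching the internal coordinate convention.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    FormatError,
    GenomicInterval,
    HomologyHit,
    MatureForm,
    Precursor,
    ReadStack,
    ValidationError,
    canonical_rna,
    check_chrom_lengths,
)

PRECURSOR_FIXED_COLUMNS = [
    "id",
    "chrom",
    "start",
    "end",
    "strand",
    "score",
    "is_known",
    "sequence",
    "arm",
    "mature_seq",
    "mature_offset",
]

STACK_COLUMNS = ["precursor_id", "library", "start", "sequence", "count", "mismatches"]
HIT_COLUMNS = ["query_id", "subject_id", "subject_species", "evalue", "db"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {', '.join(missing)}")


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


def read_precursor_table(path: Union[str, Path]) -> list[Precursor]:
    """Read the canonical precursor TSV, grouping mature rows by id.

    Count columns are every column after the fixed schema; their headers are
    the library labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PRECURSOR_FIXED_COLUMNS, f"precursor table {path}")
    libraries = [c for c in df.columns if c not in PRECURSOR_FIXED_COLUMNS]

    precursors: list[Precursor] = []
    for pid, group in df.groupby("id", sort=False):
        first = group.iloc[0]
        matures: dict[str, MatureForm] = {}
        for rownum, row in group.iterrows():
            arm = row["arm"]
            if arm in matures:
                raise ValidationError(f"row {rownum}: duplicate arm {arm} for {pid}")
            try:
                counts = {lib: int(row[lib]) for lib in libraries if row[lib] != ""}
                matures[arm] = MatureForm(
                    arm=arm,
                    ref_sequence=row["mature_seq"],
                    offset=int(row["mature_offset"]),
                    counts=counts,
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"row {rownum} (id {pid}): {exc}") from exc
        try:
            interval = GenomicInterval(
                chrom=first["chrom"],
                start=int(first["start"]),
                end=int(first["end"]),
                strand=first["strand"],
            )
            precursors.append(
                Precursor(
                    id=str(pid),
                    interval=interval,
                    sequence=first["sequence"],
                    score=float(first["score"]),
                    is_known=_parse_bool(first["is_known"]),
                    mature_5p=matures.get("5p"),
                    mature_3p=matures.get("3p"),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {group.index[0]} (id {pid}): {exc}") from exc
    return precursors


def write_precursor_table(
    precursors: Iterable[Precursor],
    path: Union[str, Path],
    libraries: Sequence[str] | None = None,
) -> None:
    """Write precursors in the canonical dialect (one row per mature form)."""
    precursors = list(precursors)
    if libraries is None:
        seen: list[str] = []
        for p in precursors:
            for m in p.matures:
                for lib in m.counts:
                    if lib not in seen:
                        seen.append(lib)
        libraries = seen
    rows = []
    for p in precursors:
        for m in p.matures:
            row = {
                "id": p.id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "strand": p.interval.strand,
                "score": p.score,
                "is_known": str(p.is_known).lower(),
                "sequence": p.sequence,
                "arm": m.arm,
                "mature_seq": m.ref_sequence,
                "mature_offset": m.offset,
            }
            for lib in libraries:
                row[lib] = m.count(lib)
            rows.append(row)
    pd.DataFrame(rows, columns=PRECURSOR_FIXED_COLUMNS + list(libraries)).to_csv(
        path, sep="\t", index=False
    )


def _format_mismatches(mismatches: frozenset[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{base}" for pos, base in sorted(mismatches))


def _parse_mismatches(text: str) -> frozenset[tuple[int, str]]:
    text = text.strip()
    if not text:
        return frozenset()
    pairs = []
    for token in text.split(";"):
        try:
            pos, base = token.split(":")
            pairs.append((int(pos), base))
        except ValueError as exc:
            raise FormatError(f"cannot parse mismatch token {token!r}") from exc
    return frozenset(pairs)


def read_read_stacks(path: Union[str, Path]) -> dict[str, ReadStack]:
    """Read the read-stack TSV into per-precursor stacks (insertion order)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, STACK_COLUMNS, f"read-stack table {path}")
    stacks: dict[str, ReadStack] = {}
    for rownum, row in df.iterrows():
        pid = row["precursor_id"]
        try:
            read = AlignedRead(
                sequence=row["sequence"],
                count=int(row["count"]),
                library=row["library"],
                start=int(row["start"]),
                mismatches=_parse_mismatches(row["mismatches"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {rownum} ({pid}): {exc}") from exc
        stacks.setdefault(pid, ReadStack(precursor_id=pid)).reads.append(read)
    return stacks


def write_read_stacks(
    stacks: Mapping[str, ReadStack] | Iterable[ReadStack], path: Union[str, Path]
) -> None:
    if isinstance(stacks, Mapping):
        stacks = stacks.values()
    rows = []
    for stack in stacks:
        for r in stack.reads:
            rows.append(
                {
                    "precursor_id": stack.precursor_id,
                    "library": r.library,
                    "start": r.start,
                    "sequence": r.sequence,
                    "count": r.count,
                    "mismatches": _format_mismatches(r.mismatches),
                }
            )
    pd.DataFrame(rows, columns=STACK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_homology_hits(path: Union[str, Path]) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, HIT_COLUMNS, f"homology table {path}")
    hits = []
    for rownum, row in df.iterrows():
        try:
            hits.append(
                HomologyHit(
                    query_id=row["query_id"],
                    subject_id=row["subject_id"],
                    subject_species=row["subject_species"],
                    evalue=float(row["evalue"]),
                    db=row["db"],
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
    return hits


def write_homology_hits(hits: Iterable[HomologyHit], path: Union[str, Path]) -> None:
    rows = [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "subject_species": h.subject_species,
            "evalue": repr(h.evalue),
            "db": h.db,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_chrom_lengths(path: Union[str, Path]) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["chrom", "length_bp"], f"chromosome-length table {path}")
    try:
        return check_chrom_lengths(
            {row["chrom"]: int(row["length_bp"]) for _, row in df.iterrows()}
        )
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def write_chrom_lengths(lengths: Mapping[str, int], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [{"chrom": c, "length_bp": n} for c, n in lengths.items()],
        columns=["chrom", "length_bp"],
    ).to_csv(path, sep="\t", index=False)


def read_snr_table(path: Union[str, Path]) -> list[tuple[float, float]]:
    """Read (cutoff, snr) rows for score-threshold selection."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["cutoff", "snr"], f"SNR table {path}")
    return [(float(r["cutoff"]), float(r["snr"])) for _, r in df.iterrows()]


def write_snr_table(
    rows: Iterable[tuple[float, float]], path: Union[str, Path]
) -> None:
    pd.DataFrame(
        [{"cutoff": c, "snr": s} for c, s in rows], columns=["cutoff", "snr"]
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """FASTA into {first header token: canonical RNA sequence}."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = canonical_rna(str(record.seq))
    return out


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(items: Iterable, path: Union[str, Path]) -> None:
    """Write precursors or clusters as BED6 (0-based half-open).

    Precursors use their assigned name (falling back to id) and
    ``min(1000, round(score))`` as the BED score.  Clusters span the envelope
    of their members, with the member names joined by commas.
    """
    lines = []
    for item in items:
        if isinstance(item, Precursor):
            name = item.name or item.id
            score = min(1000, round(item.score))
            iv = item.interval
        else:  # Cluster-like: members + envelope interval
            iv = item.interval
            name = ",".join(p.name or p.id for p in item.members)
            score = len(item.members)
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
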