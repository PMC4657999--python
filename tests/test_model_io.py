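"""Domain-type invariants and canonical-dialect round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovimir import io as ovio
from ovimir.genome import Cluster
from ovimir.model import (
    AlignedRead,
    FormatError,
    GenomicInterval,
    HomologyHit,
    MatureForm,
    Precursor,
    ValidationError,
    canonical_rna,
)

from conftest import make_precursor


class TestTypes:
    def test_sequences_are_canonicalized_to_uppercase_rna(self):
        assert canonical_rna("acgt") == "ACGU"
        with pytest.raises(ValidationError):
            canonical_rna("ACGX")

    @pytest.mark.parametrize(
        "start,end,strand",
        [(100, 90, "+"), (-1, 10, "+"), (5, 5, "+"), (0, 10, "fwd")],
    )
    def test_interval_invariants_rejected(self, start, end, strand):
        with pytest.raises(ValidationError):
            GenomicInterval(chrom="1", start=start, end=end, strand=strand)

    def test_mature_length_window_enforced(self):
        with pytest.raises(ValidationError):
            MatureForm(arm="5p", ref_sequence="ACGUACGUACGUAC", offset=0)  # 14 nt
        with pytest.raises(ValidationError):
            MatureForm(arm="5p", ref_sequence="A" * 33, offset=0)

    def test_precursor_requires_matching_mature_sequence(self):
        p = make_precursor(seq3="ACGUACGUACGUACGUACGUA")
        bad = MatureForm(arm="5p", ref_sequence="A" * 20, offset=0)
        with pytest.raises(ValidationError):
            Precursor(
                id="x",
                interval=p.interval,
                sequence=p.sequence,
                score=1.0,
                mature_5p=bad,
            )

    def test_read_mismatch_positions_bounded(self):
        with pytest.raises(ValidationError):
            AlignedRead(
                sequence="ACGU" * 5, count=1, library="LV", start=0,
                mismatches={(25, "A")},
            )

    def test_homology_hit_rejects_unknown_db_and_nonpositive_evalue(self):
        with pytest.raises(ValidationError):
            HomologyHit("q", "s", "bta", 1e-5, "blastx")
        with pytest.raises(ValidationError):
            HomologyHit("q", "s", "bta", 0.0, "mirbase")


def _random_precursors(rng, n):
    out = []
    for i in range(n):
        bases = "ACGU"
        seq3 = "".join(rng.choice(list(bases), size=int(rng.integers(18, 25))))
        two = rng.random() < 0.5
        counts3 = {"LV": int(rng.integers(0, 500)), "GL": int(rng.integers(0, 500))}
        counts5 = (
            {"LV": int(rng.integers(0, 500)), "GL": int(rng.integers(0, 500))}
            if two
            else None
        )
        out.append(
            make_precursor(
                pid=f"p{i}",
                seq3=seq3,
                counts3=counts3,
                counts5=counts5,
                chrom=str(rng.integers(1, 5)),
                start=int(rng.integers(0, 10**6)),
                strand="+" if rng.random() < 0.5 else "-",
                score=float(np.round(rng.uniform(0, 99), 3)),
                is_known=bool(rng.random() < 0.2),
            )
        )
    return out


class TestPrecursorTable:
    def test_round_trip_preserves_structure(self, tmp_path):
        rng = np.random.default_rng(42)
        original = _random_precursors(rng, 50)
        path = tmp_path / "precursors.tsv"
        ovio.write_precursor_table(original, path, libraries=("LV", "GL"))
        restored = ovio.read_precursor_table(path)
        assert len(restored) == len(original)
        for a, b in zip(original, restored):
            assert a.id == b.id
            assert a.interval == b.interval
            assert a.sequence == b.sequence
            assert a.score == b.score
            assert a.is_known == b.is_known
            for ma, mb in zip(a.matures, b.matures):
                assert (ma.arm, ma.ref_sequence, ma.offset) == (
                    mb.arm,
                    mb.ref_sequence,
                    mb.offset,
                )
                assert {lib: ma.count(lib) for lib in ("LV", "GL")} == {
                    lib: mb.count(lib) for lib in ("LV", "GL")
                }

    def test_rows_sharing_id_become_one_precursor_with_both_arms(self, tmp_path):
        p = make_precursor(
            pid="p1",
            seq3="ACGUACGUACGUACGUACGUA",
            counts3={"LV": 5},
            counts5={"LV": 9},
        )
        path = tmp_path / "t.tsv"
        ovio.write_precursor_table([p], path)
        (restored,) = ovio.read_precursor_table(path)
        assert restored.mature_5p is not None and restored.mature_3p is not None

    def test_coordinate_violation_names_the_row(self, tmp_path):
        p = make_precursor(seq3="ACGUACGUACGUACGUACGUA", counts3={"LV": 5})
        path = tmp_path / "t.tsv"
        ovio.write_precursor_table([p], path)
        text = path.read_text().splitlines()
        text[1] = text[1].replace("\t1000\t", "\t-7\t", 1)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValidationError, match="row"):
            ovio.read_precursor_table(path)

    def test_missing_column_is_a_format_error_naming_it(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id\tchrom\tstart\n")
        with pytest.raises(FormatError, match="strand"):
            ovio.read_precursor_table(path)


class TestStacksAndHits:
    def test_stack_round_trip_preserves_reads_and_mismatches(self, tmp_path):
        from ovimir.model import ReadStack

        stack = ReadStack(
            precursor_id="p1",
            reads=[
                AlignedRead("ACGUACGUACGUACGUA", 10, "LV", 4),
                AlignedRead(
                    "ACGAACGUACGUACGUA", 3, "GL", 4, mismatches={(4, "A")}
                ),
            ],
        )
        path = tmp_path / "stacks.tsv"
        ovio.write_read_stacks({"p1": stack}, path)
        restored = ovio.read_read_stacks(path)
        assert restored["p1"].reads == stack.reads

    def test_homology_round_trip_preserves_evalues_exactly(self, tmp_path):
        hits = [
            HomologyHit("q1", "s1", "bta", 4.2e-19, "mirbase"),
            HomologyHit("q2", "1:100-200", "oar", 2e-8, "genome_self"),
        ]
        path = tmp_path / "hits.tsv"
        ovio.write_homology_hits(hits, path)
        assert ovio.read_homology_hits(path) == hits


class TestBed:
    def test_precursor_coordinates_pass_through(self, tmp_path):
        p = make_precursor(
            pid="mir-x", seq3="ACGUACGUACGUACGUACGUA", chrom="18",
            start=100, strand="-", score=1234.7,
        )
        path = tmp_path / "out.bed"
        ovio.write_bed([p], path)
        fields = path.read_text().strip().split("\t")
        assert fields[0] == "18"
        assert fields[1] == "100"
        assert int(fields[2]) == 100 + len(p.sequence)
        assert fields[3] == "mir-x"
        assert fields[4] == "1000"  # capped
        assert fields[5] == "-"

    def test_empty_list_writes_empty_file(self, tmp_path):
        path = tmp_path / "out.bed"
        ovio.write_bed([], path)
        assert path.read_text() == ""

    def test_cluster_line_spans_member_envelope(self, tmp_path):
        a = make_precursor(pid="a", seq3="ACGUACGUACGUACGUACGUA", start=100)
        b = make_precursor(pid="b", seq3="ACGAACGUACGUACGUACGUA", start=5000)
        cluster = Cluster(members=[a, b])
        path = tmp_path / "out.bed"
        ovio.write_bed([cluster], path)
        fields = path.read_text().strip().split("\t")
        assert (fields[1], fields[2]) == ("100", str(5000 + len(b.sequence)))
        assert fields[3] == "a,b"


@settings(max_examples=30, derandomize=True)
@given(
    start=st.integers(min_value=0, max_value=10**6),
    length=st.integers(min_value=18, max_value=24),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_serialization_round_trip_property(tmp_path_factory, start, length, seed):
    """Any valid precursor survives write-then-read unchanged."""
    rng = np.random.default_rng(seed)
    seq3 = "".join(rng.choice(list("ACGU"), size=length))
    p = make_precursor(
        pid="p", seq3=seq3, counts3={"LV": int(rng.integers(0, 10**6))}, start=start
    )
    path = tmp_path_factory.mktemp("rt") / "p.tsv"
    ovio.write_precursor_table([p], path)
    (q,) = ovio.read_precursor_table(path)
    assert (q.interval, q.sequence, q.mature_3p.ref_sequence) == (
        p.interval,
        p.sequence,
        p.mature_3p.ref_sequence,
    )
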