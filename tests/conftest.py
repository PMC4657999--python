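import pytest

from ovimir.model import GenomicInterval, MatureForm, Precursor
from ovimir.pipeline import Inputs, run_pipeline
from ovimir.simulate import SimConfig, simulate

_RC = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def make_precursor(
    pid="p1",
    seq5=None,
    seq3=None,
    counts5=None,
    counts3=None,
    chrom="1",
    start=1000,
    strand="+",
    score=50.0,
    is_known=False,
):
    """Build a valid hairpin precursor around the requested mature arm(s).

    Arms without a requested sequence get the reverse complement of the
    other arm (a star sequence) and, if counts are given for them, become
    mature forms too.
    """
    if seq5 is None and seq3 is None:
        raise ValueError("need at least one mature sequence")
    arm5 = seq5 if seq5 is not None else revcomp(seq3)
    arm3 = seq3 if seq3 is not None else revcomp(seq5)
    loop = "AUCGAUCGUU"
    hairpin = "GGAC" + arm5 + loop + arm3 + "CAGG"
    off5 = 4
    off3 = 4 + len(arm5) + len(loop)
    m5 = (
        MatureForm(arm="5p", ref_sequence=arm5, offset=off5, counts=counts5 or {})
        if (seq5 is not None or counts5)
        else None
    )
    m3 = (
        MatureForm(arm="3p", ref_sequence=arm3, offset=off3, counts=counts3 or {})
        if (seq3 is not None or counts3)
        else None
    )
    return Precursor(
        id=pid,
        interval=GenomicInterval(
            chrom=chrom, start=start, end=start + len(hairpin), strand=strand
        ),
        sequence=hairpin,
        score=score,
        is_known=is_known,
        mature_5p=m5,
        mature_3p=m3,
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic scenario (the study conditions), seed 1."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline run on the default scenario."""
    r = default_sim
    inputs = Inputs(
        precursors=r.precursors,
        stacks=r.stacks,
        hits=r.hits,
        chrom_lengths=r.chrom_lengths,
        snr_rows=r.snr_rows,
        homolog_catalog=r.homolog_catalog,
    )
    return run_pipeline(inputs)
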