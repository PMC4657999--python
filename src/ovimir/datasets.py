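"""Small bundled datasets.

``lv_qpcr_panels`` returns the stem-loop qRT-PCR threshold cycles measured
in sheep left ventricle for the validation assays: one panel of 10 novel
mature miRNAs and one panel of 4 known ones, each run against a U6 snRNA
control.  Values are as published for the validation experiment this
package's quantification module mirrors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quantify import CtRecord

__all__ = ["lv_qpcr_panels", "LV_LIBRARY_READS", "GLOBAL_LIBRARY_READS"]


def lv_qpcr_panels() -> dict[str, list[CtRecord]]:
    """{panel name -> Ct records (control assay 'U6' included per panel)}."""
    with resources.files("ovimir.data").joinpath("lv_qpcr_ct.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    panels: dict[str, list[CtRecord]] = {}
    for _, row in df.iterrows():
        panels.setdefault(row["panel"], []).append(
            CtRecord(assay=row["assay"], ct=float(row["ct"]), sd=float(row["sd"]))
        )
    return panels


# Published sequencing summary for the two libraries: raw read totals,
# reads surviving the mappability filters, reads assigned to a mature
# 5p/3p sequence, and reads on novel vs known matures.
LV_LIBRARY_READS = {
    "raw": 9_512_054,
    "mappable": 5_537_088,
    "mature_mapped": 3_927_458,
    "novel": 1_607_604,
    "known": 2_319_350,
}
GLOBAL_LIBRARY_READS = {
    "raw": 11_831_013,
    "mappable": 9_089_864,
    "mature_mapped": 6_663_266,
    "novel": 1_900_117,
    "known": 4_762_811,
}
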