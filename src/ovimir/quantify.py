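"""No-replicate quantification: median-of-ratios fold change and qPCR dCt.

Two unreplicated RNA-seq libraries are compared by first estimating one
size factor per library as the median, over features with positive counts
in every library, of the ratio of the feature's count to its cross-library
geometric mean — the classic median-of-ratios estimator.  Fold change is
the ratio of normalized counts; no pseudocount is added by default, so
all-or-nothing features are flagged (0 or infinity) rather than smoothed.

Stem-loop qRT-PCR results are called expressed at threshold cycle Ct < 35,
and quantified relative to the U6 small nuclear RNA control as
``2 ** -(Ct_assay - Ct_control)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import ConfigurationError, ValidationError

__all__ = [
    "CtRecord",
    "QpcrCall",
    "size_factors",
    "fold_change",
    "qpcr_quantify",
]


class NormalizationError(ValueError):
    """Median-of-ratios normalization is impossible on this matrix."""


def _validate_matrix(matrix: Mapping[str, Mapping[str, int]]) -> list[str]:
    if not matrix:
        raise ValidationError("empty count matrix")
    libraries: list[str] = []
    for feature, counts in matrix.items():
        for lib, n in counts.items():
            if n < 0 or int(n) != n:
                raise ValidationError(
                    f"count for {feature}/{lib} must be a nonnegative integer"
                )
            if lib not in libraries:
                libraries.append(lib)
    return libraries


def size_factors(
    matrix: Mapping[str, Mapping[str, int]],
    libraries: Sequence[str] | None = None,
) -> dict[str, float]:
    """Median-of-ratios size factor per library.

    For each library j the factor is the median over features i — using
    only features positive in every library — of ``count[i][j] / gm_i``
    where ``gm_i`` is the geometric mean of feature i across libraries.
    """
    found = _validate_matrix(matrix)
    libraries = list(libraries) if libraries is not None else found
    rows = []
    for feature, counts in matrix.items():
        vec = [counts.get(lib, 0) for lib in libraries]
        if all(v > 0 for v in vec):
            rows.append(vec)
    if not rows:
        raise NormalizationError(
            "no feature has positive counts in every library; "
            "median-of-ratios normalization is impossible"
        )
    arr = np.asarray(rows, dtype=float)
    log_gm = np.mean(np.log(arr), axis=1, keepdims=True)
    ratios = np.exp(np.log(arr) - log_gm)
    factors = np.median(ratios, axis=0)
    return dict(zip(libraries, factors.tolist()))


def fold_change(
    matrix: Mapping[str, Mapping[str, int]],
    factors: Mapping[str, float],
    pair: Sequence[str],
    pseudocount: float = 0.0,
) -> dict[str, float]:
    """Normalized fold change A:B per feature.

    ``FC = (count_A / factor_A) / (count_B / factor_B)``.  With no
    pseudocount (the default) a zero denominator is flagged as ``inf``, a
    zero numerator gives 0.0, and 0/0 gives ``nan``.
    """
    if len(pair) != 2:
        raise ConfigurationError("fold change needs an ordered pair of libraries")
    lib_a, lib_b = pair
    for lib in pair:
        if lib not in factors:
            raise ConfigurationError(f"no size factor for library {lib!r}")
        if factors[lib] <= 0:
            raise ValidationError(f"size factor for {lib!r} must be positive")
    out: dict[str, float] = {}
    for feature, counts in matrix.items():
        if lib_a not in counts and lib_b not in counts:
            raise ConfigurationError(
                f"feature {feature!r} has neither library of the pair"
            )
        num = (counts.get(lib_a, 0) + pseudocount) / factors[lib_a]
        den = (counts.get(lib_b, 0) + pseudocount) / factors[lib_b]
        if den == 0:
            out[feature] = math.nan if num == 0 else math.inf
        else:
            out[feature] = num / den
    return out


@dataclass(frozen=True)
class CtRecord:
    """One qPCR assay: threshold cycle and its standard deviation."""

    assay: str
    ct: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValidationError(f"Ct must be positive, got {self.ct}")
        if self.sd < 0:
            raise ValidationError(f"Ct standard deviation must be nonnegative")


@dataclass(frozen=True)
class QpcrCall:
    assay: str
    expressed: bool
    delta_ct: float
    rq: float  # relative quantity, 2 ** -delta_ct


def qpcr_quantify(
    records: Sequence[CtRecord],
    control: str = "U6",
    ct_max: float = 35.0,
) -> dict[str, QpcrCall]:
    """Expression calls and relative quantities against a control assay.

    An assay is expressed iff its Ct is strictly below ``ct_max``;
    ``delta_ct = ct_assay - ct_control`` and ``rq = 2 ** -delta_ct`` (so the
    control itself has rq 1).
    """
    by_name = {r.assay: r for r in records}
    if control not in by_name:
        raise ConfigurationError(f"control assay {control!r} missing from records")
    ct_control = by_name[control].ct
    out = {}
    for r in records:
        delta = r.ct - ct_control
        out[r.assay] = QpcrCall(
            assay=r.assay,
            expressed=r.ct < ct_max,
            delta_ct=delta,
            rq=2.0 ** (-delta),
        )
    return out
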