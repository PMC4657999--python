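"""Summary statistics for reports: read-length distribution and rendering
helpers."""

from __future__ import annotations

from typing import Iterable, Mapping

from .model import AlignedRead, NoDataError

__all__ = ["length_distribution", "as_percent"]


def length_distribution(
    reads: Iterable[AlignedRead],
    band: tuple[int, int] = (18, 24),
) -> tuple[dict[int, int], float]:
    """Count-weighted read-length histogram and the fraction of reads whose
    length falls in the closed interval ``band`` (default 18-24 nt, the
    canonical mature-miRNA window)."""
    histogram: dict[int, int] = {}
    for r in reads:
        n = len(r.sequence)
        histogram[n] = histogram.get(n, 0) + r.count
    total = sum(histogram.values())
    if total == 0:
        raise NoDataError("no reads for length distribution")
    lo, hi = band
    in_band = sum(c for n, c in histogram.items() if lo <= n <= hi)
    return dict(sorted(histogram.items())), in_band / total


def as_percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Render a ratio as a percentage at ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * numerator / denominator, ndigits)
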