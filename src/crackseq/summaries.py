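"""Assembly- and run-level summary statistics.

Reproduces the arithmetic of a transcriptome summary table: sequence
counts, total and mean lengths (mean rounded half-up to an integer, the
convention of such tables), a length histogram, an N50 extra, and total
sequenced bases from read count x read length. Integer arithmetic
throughout so reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .count_model import UnigeneRecord

__all__ = ["AssemblySummary", "assembly_stats", "read_totals", "n50", "mean_length"]


def mean_length(total_length_bp: int, n_sequences: int) -> int:
    """total/n rounded half-up to an integer."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    return int((Decimal(total_length_bp) / Decimal(n_sequences)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP
    ))


@dataclass(frozen=True)
class AssemblySummary:
    n_sequences: int
    total_length_bp: int
    mean_length_bp: int
    n50_bp: int
    #: list of (bin_start_bp, bin_end_bp_exclusive, count)
    length_histogram: tuple[tuple[int, int, int], ...]


def n50(lengths: Sequence[int]) -> int:
    """Length such that contigs at least this long hold >= half the bases."""
    if not lengths:
        raise ValueError("no lengths given")
    acc = 0
    half = sum(lengths) / 2
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= half:
            return L
    return 0  # unreachable


def assembly_stats(
    records: Iterable[UnigeneRecord],
    min_length_bp: int = 200,
    bin_width_bp: int = 200,
) -> AssemblySummary:
    """Summary statistics over records passing the minimum-length filter.

    Histogram bins are ``bin_width_bp`` wide starting at ``min_length_bp``;
    the last bin is open-ended (end reported as the max length + 1).
    """
    lengths = [r.length_bp for r in records if r.length_bp >= min_length_bp]
    if not lengths:
        raise ValueError(f"no records with length >= {min_length_bp} bp")
    total = sum(lengths)
    n = len(lengths)
    lmax = max(lengths)
    bins: list[tuple[int, int, int]] = []
    start = min_length_bp
    while start <= lmax:
        end = start + bin_width_bp
        count = sum(1 for L in lengths if start <= L < end)
        bins.append((start, min(end, lmax + 1) if end > lmax else end, count))
        start = end
    return AssemblySummary(
        n_sequences=n,
        total_length_bp=total,
        mean_length_bp=mean_length(total, n),
        n50_bp=n50(lengths),
        length_histogram=tuple(bins),
    )


def read_totals(n_reads: int, read_length_bp: int) -> int:
    """Total sequenced bases: n_reads * read_length_bp."""
    if n_reads < 1 or read_length_bp < 1:
        raise ValueError(
            f"n_reads and read_length_bp must be positive, got {n_reads}, {read_length_bp}"
        )
    return n_reads * read_length_bp
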