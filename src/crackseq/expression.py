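"""RPKM, fold change with zero substitution, and threshold DEG calling.

Expression is normalized as RPKM (reads per kilobase of transcript per
million mapped reads): 1e9 * count / (total_mapped * length_bp). Fold
change is the ratio of RPKM values between the two libraries; whenever one
RPKM is exactly zero a small positive substitute (default 0.001) replaces
it so the log2 ratio is defined. A unigene is called differentially
expressed when its step-up FDR is at most ``fdr_max`` (default 0.001) and
|log2 ratio| is at least ``min_abs_log2fc`` (default 1, i.e. two-fold),
both thresholds inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .ac_test import ac_two_sided_pvalue, bh_fdr
from .count_model import CountTableLike, LibraryPair, validate_count_table

__all__ = [
    "DegThresholds",
    "rpkm",
    "log2_fold_change",
    "call_degs",
    "partition_degs",
]

#: Columns of the DataFrame produced by :func:`call_degs`.
RESULT_COLUMNS = (
    "unigene_id",
    "rpkm_1",
    "rpkm_2",
    "log2fc",
    "p_value",
    "fdr",
    "is_deg",
    "direction",
)


@dataclass(frozen=True)
class DegThresholds:
    """DEG-calling thresholds (defaults: FDR <= 0.001, >= two-fold)."""

    fdr_max: float = 0.001
    min_abs_log2fc: float = 1.0
    zero_substitute: float = 0.001

    def __post_init__(self):
        if not (0.0 < self.fdr_max <= 1.0):
            raise ValueError(f"fdr_max must be in (0, 1], got {self.fdr_max}")
        if self.min_abs_log2fc < 0:
            raise ValueError(f"min_abs_log2fc must be >= 0, got {self.min_abs_log2fc}")
        if self.zero_substitute <= 0:
            raise ValueError(f"zero_substitute must be > 0, got {self.zero_substitute}")


def rpkm(count: int, length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase per million mapped reads: 1e9*count/(N*L)."""
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    if total_mapped < 1:
        raise ValueError(f"total_mapped must be >= 1, got {total_mapped}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return 1e9 * count / (total_mapped * length_bp)


def log2_fold_change(rpkm_1: float, rpkm_2: float, zero_substitute: float = 0.001) -> float:
    """log2(RPKM2/RPKM1), substituting ``zero_substitute`` for exact zeros.

    Positive values mean higher expression in library 2.
    """
    if rpkm_1 < 0 or rpkm_2 < 0:
        raise ValueError("RPKM values must be >= 0")
    if zero_substitute <= 0:
        raise ValueError("zero_substitute must be > 0")
    a = rpkm_1 if rpkm_1 > 0 else zero_substitute
    b = rpkm_2 if rpkm_2 > 0 else zero_substitute
    return math.log2(b / a)


LengthsLike = Union[Mapping[str, int], pd.Series, pd.DataFrame]


def _lengths_as_mapping(lengths: LengthsLike) -> Mapping[str, int]:
    if isinstance(lengths, pd.DataFrame):
        return dict(zip(lengths.iloc[:, 0].astype(str), lengths.iloc[:, 1].astype(int)))
    if isinstance(lengths, pd.Series):
        return lengths.astype(int).to_dict()
    return lengths


def call_degs(
    counts: CountTableLike,
    lengths: LengthsLike,
    pair: LibraryPair,
    thresholds: DegThresholds = DegThresholds(),
) -> pd.DataFrame:
    """Full per-unigene differential-expression analysis.

    Computes RPKM for both libraries, the zero-substituted log2 fold
    change, the two-sided significance p-value, Benjamini–Hochberg FDR over
    all rows jointly, and the DEG call. Rows with zero counts in both
    libraries carry p-value 1 (no evidence either way). Output row order
    matches input order.

    Parameters
    ----------
    counts
        Count table (``validate_count_table`` input forms accepted).
    lengths
        unigene_id -> length_bp mapping (or 2-column DataFrame / Series).
    pair
        Library totals and labels.
    thresholds
        DEG thresholds; defaults are FDR <= 0.001 and |log2fc| >= 1.

    Returns
    -------
    DataFrame with columns ``unigene_id, rpkm_1, rpkm_2, log2fc, p_value,
    fdr, is_deg, direction``.
    """
    table = validate_count_table(counts, pair)
    lmap = _lengths_as_mapping(lengths)
    missing = [uid for uid in table["unigene_id"] if uid not in lmap]
    if missing:
        raise ValueError(f"no length for unigene(s): {missing[:5]}" + ("..." if len(missing) > 5 else ""))

    ids = table["unigene_id"].to_numpy()
    x = table["count_1"].to_numpy()
    i = table["count_2"].to_numpy()
    length = np.array([lmap[uid] for uid in ids], dtype=float)
    if np.any(length < 1):
        raise ValueError("all unigene lengths must be >= 1")

    rpkm_1 = 1e9 * x / (pair.n1 * length)
    rpkm_2 = 1e9 * i / (pair.n2 * length)
    sub = thresholds.zero_substitute
    log2fc = np.log2(np.where(rpkm_2 > 0, rpkm_2, sub) / np.where(rpkm_1 > 0, rpkm_1, sub))

    pvals = np.array(
        [
            1.0 if (xv == 0 and iv == 0) else ac_two_sided_pvalue(int(xv), int(iv), pair.n1, pair.n2)
            for xv, iv in zip(x, i)
        ]
    )
    fdr = bh_fdr(pvals)

    is_deg = (fdr <= thresholds.fdr_max) & (np.abs(log2fc) >= thresholds.min_abs_log2fc)
    # a DEG with log2fc == 0 (possible only at min_abs_log2fc == 0) has no direction
    direction = np.select(
        [is_deg & (log2fc > 0), is_deg & (log2fc < 0)], ["up", "down"], default="none"
    )

    return pd.DataFrame(
        {
            "unigene_id": ids,
            "rpkm_1": rpkm_1,
            "rpkm_2": rpkm_2,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "is_deg": is_deg,
            "direction": direction,
        }
    )


def partition_degs(results: pd.DataFrame) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) over called DEGs; up + down = total."""
    deg = results[results["is_deg"]]
    n_up = int((deg["direction"] == "up").sum())
    n_down = int((deg["direction"] == "down").sum())
    return n_up, n_down, n_up + n_down
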