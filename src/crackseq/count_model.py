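"""Domain types and validated containers shared by all pipeline stages.

The pipeline compares two un-replicated sequencing libraries (e.g. pericarp
from non-cracking vs cracking fruit). Each unigene carries one integer read
count per library; library totals N1, N2 are the numbers of clean reads
mapped to all unigenes in each sample. Counts are strict integers because
the downstream significance formula involves factorials of counts:
integral-valued floats are narrowed to int, fractional values rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "LibraryPair",
    "UnigeneRecord",
    "CountRecord",
    "ExpressionResult",
    "AnnotationHit",
    "KNOWN_DATABASES",
    "validate_count_table",
]

#: Closed set of annotation databases the pipeline understands.
KNOWN_DATABASES = ("NR", "SwissProt", "KEGG", "COG", "GO")


def _as_int(value, what: str) -> int:
    """Narrow an integral value to int; reject fractional or negative-typed junk."""
    if isinstance(value, bool):
        raise TypeError(f"{what} must be an integer, got bool")
    if isinstance(value, int):
        return value
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise TypeError(f"{what} must be an integer, got {value!r}") from None
    if not f.is_integer():
        raise ValueError(f"{what} must be an integer, got {value!r}")
    return int(f)


@dataclass(frozen=True)
class LibraryPair:
    """The two libraries being compared.

    ``n1``/``n2`` are the total clean reads mapped to all unigenes in each
    sample; they are the N1, N2 of the significance formula and the
    denominators of RPKM.
    """

    label_1: str
    label_2: str
    n1: int
    n2: int

    def __post_init__(self):
        object.__setattr__(self, "n1", _as_int(self.n1, "n1"))
        object.__setattr__(self, "n2", _as_int(self.n2, "n2"))
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError(f"library totals must be >= 1, got n1={self.n1}, n2={self.n2}")
        if not self.label_1 or not self.label_2:
            raise ValueError("library labels must be non-empty")
        if self.label_1 == self.label_2:
            raise ValueError(f"library labels must be distinct, both are {self.label_1!r}")


@dataclass(frozen=True)
class UnigeneRecord:
    """One assembled transcript (unigene): id, length, optional sequence."""

    unigene_id: str
    length_bp: int
    sequence: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "length_bp", _as_int(self.length_bp, "length_bp"))
        if self.length_bp < 1:
            raise ValueError(f"{self.unigene_id}: length_bp must be >= 1, got {self.length_bp}")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.length_bp:
                raise ValueError(
                    f"{self.unigene_id}: sequence length {len(seq)} != length_bp {self.length_bp}"
                )
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{self.unigene_id}: non-ACGTN characters {sorted(bad)}")
            object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class CountRecord:
    """Per-unigene read counts: ``x`` in library 1, ``i`` in library 2."""

    unigene_id: str
    x: int
    i: int

    def __post_init__(self):
        object.__setattr__(self, "x", _as_int(self.x, f"{self.unigene_id}: x"))
        object.__setattr__(self, "i", _as_int(self.i, f"{self.unigene_id}: i"))
        if self.x < 0 or self.i < 0:
            raise ValueError(f"{self.unigene_id}: counts must be >= 0, got x={self.x}, i={self.i}")


@dataclass(frozen=True)
class ExpressionResult:
    """Per-unigene differential-expression outcome.

    ``log2fc`` is log2(adjusted RPKM2 / adjusted RPKM1): positive means
    higher expression in library 2. ``direction`` is ``up``/``down`` only
    for called DEGs, else ``none``.
    """

    unigene_id: str
    rpkm_1: float
    rpkm_2: float
    log2fc: float
    p_value: float
    fdr: float
    is_deg: bool
    direction: str

    def __post_init__(self):
        if self.rpkm_1 < 0 or self.rpkm_2 < 0:
            raise ValueError(f"{self.unigene_id}: RPKM must be >= 0")
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.unigene_id}: p_value and fdr must lie in [0, 1]")
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"{self.unigene_id}: bad direction {self.direction!r}")
        want = "none"
        if self.is_deg and self.log2fc > 0:
            want = "up"
        elif self.is_deg and self.log2fc < 0:
            want = "down"
        if self.direction != want:
            raise ValueError(
                f"{self.unigene_id}: direction {self.direction!r} inconsistent with "
                f"is_deg={self.is_deg}, log2fc={self.log2fc}"
            )


@dataclass(frozen=True)
class AnnotationHit:
    """One database match for a unigene (post E-value filtering)."""

    unigene_id: str
    database: str
    description: str
    e_value: float

    def __post_init__(self):
        if self.database not in KNOWN_DATABASES:
            raise ValueError(
                f"{self.unigene_id}: unknown database {self.database!r}; "
                f"expected one of {KNOWN_DATABASES}"
            )
        if self.e_value < 0:
            raise ValueError(f"{self.unigene_id}: e_value must be >= 0, got {self.e_value}")


CountTableLike = Union[pd.DataFrame, Iterable[CountRecord]]

#: Canonical column names of a validated count table.
COUNT_COLUMNS = ("unigene_id", "count_1", "count_2")


def validate_count_table(records: CountTableLike, pair: LibraryPair) -> pd.DataFrame:
    """Validate per-unigene counts against a library pair.

    Accepts an iterable of :class:`CountRecord` or a DataFrame whose first
    three columns are id, count-in-library-1, count-in-library-2. Returns a
    canonical DataFrame with columns ``unigene_id, count_1, count_2``
    (integer dtype), preserving input order. Idempotent on its own output.

    Raises
    ------
    ValueError
        On empty input, duplicate unigene ids (named in the message),
        negative or fractional counts, or a count exceeding its library
        total.
    """
    if isinstance(records, pd.DataFrame):
        if records.shape[1] < 3:
            raise ValueError("count table needs 3 columns: id, count_1, count_2")
        ids = records.iloc[:, 0].astype(str).tolist()
        xs = records.iloc[:, 1].tolist()
        iis = records.iloc[:, 2].tolist()
    else:
        recs = list(records)
        ids = [r.unigene_id for r in recs]
        xs = [r.x for r in recs]
        iis = [r.i for r in recs]
    if not ids:
        raise ValueError("count table is empty")

    seen: set[str] = set()
    for uid in ids:
        if uid in seen:
            raise ValueError(f"duplicate unigene_id {uid!r} in count table")
        seen.add(uid)

    xs = [_as_int(v, f"{uid}: count_1") for uid, v in zip(ids, xs)]
    iis = [_as_int(v, f"{uid}: count_2") for uid, v in zip(ids, iis)]
    for uid, x, i in zip(ids, xs, iis):
        if x < 0 or i < 0:
            raise ValueError(f"{uid}: negative count (x={x}, i={i})")
        if x > pair.n1:
            raise ValueError(f"{uid}: count_1={x} exceeds library total n1={pair.n1}")
        if i > pair.n2:
            raise ValueError(f"{uid}: count_2={i} exceeds library total n2={pair.n2}")

    return pd.DataFrame({"unigene_id": ids, "count_1": xs, "count_2": iis})
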