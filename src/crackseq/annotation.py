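"""Annotation merging, hit-rate summaries, and candidate-gene classification.

A de novo assembly is annotated against several protein databases. When a
unigene has hits in more than one database, one functional description is
adopted by database priority (NR, then Swiss-Prot, KEGG, COG; GO last),
taking the best E-value hit within the winning database. Summaries report
per-database hit counts as percentages of the assembly (half-up rounding to
two decimals, matching the usual printed precision).

Differentially expressed unigenes are then screened for candidate
fruit-cracking genes with ordered keyword/regex rules over the adopted
descriptions, grouping gene families into five mechanism pathways: water
transport, GA metabolism, ABA metabolism, Ca transport and cell wall
metabolism. Each DEG is assigned to at most one rule (first match wins).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .count_model import AnnotationHit, KNOWN_DATABASES

__all__ = [
    "MergedAnnotation",
    "CandidateRule",
    "DEFAULT_PRIORITY",
    "DEFAULT_RULES",
    "percent_of",
    "filter_hits",
    "merge_annotations",
    "summarize_hits",
    "summarize_hit_counts",
    "summarize_categories",
    "classify_candidates",
]

#: Database priority used to adopt one description per unigene.
DEFAULT_PRIORITY = ("NR", "SwissProt", "KEGG", "COG", "GO")

#: Default E-value cutoff for considering a hit significant.
DEFAULT_EVALUE_MAX = 1e-5


def percent_of(count: int, base: int, ndigits: int = 2) -> float:
    """100*count/base rounded half-up to ``ndigits`` decimals."""
    if base <= 0:
        raise ValueError(f"percentage base must be positive, got {base}")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(base)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MergedAnnotation:
    """Adopted annotation for one unigene, with all retained hits."""

    unigene_id: str
    source_db: str
    description: str
    e_value: float
    all_hits: tuple[AnnotationHit, ...] = ()


@dataclass(frozen=True)
class CandidateRule:
    """One (pathway, gene family) keyword rule.

    ``pattern`` is a case-insensitive regular expression searched against
    merged descriptions. ``example`` is a plain token guaranteed to match
    the pattern, used when generating synthetic annotations; it defaults to
    the family label when that matches.
    """

    pathway: str
    family_label: str
    pattern: str
    example: Optional[str] = None

    def __post_init__(self):
        if not self.family_label:
            raise ValueError("family_label must be non-empty")
        try:
            rx = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"bad pattern for {self.family_label}: {exc}") from None
        ex = self.example
        if ex is None and rx.search(self.family_label):
            ex = self.family_label
        if ex is not None and not rx.search(ex):
            raise ValueError(
                f"{self.family_label}: example {ex!r} does not match pattern {self.pattern!r}"
            )
        object.__setattr__(self, "example", ex)

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


#: Gene-family rules for the five fruit-cracking candidate pathways.
DEFAULT_RULES = (
    CandidateRule("water transport", "PIP", r"\bPIP\d*", "PIP2"),
    CandidateRule("water transport", "NIP", r"\bNIP\d*", "NIP1"),
    CandidateRule("water transport", "SIP", r"\bSIP\d*", "SIP1"),
    CandidateRule("water transport", "AQP", r"aquaporin|\bAQP\d*", "aquaporin"),
    CandidateRule("GA metabolism", "KS", r"ent-kaurene synthase|\bKS\b", "ent-kaurene synthase"),
    CandidateRule("GA metabolism", "GA2ox", r"gibberellin 2[- ]?(?:beta[- ]?)?(?:di)?oxidase|\bGA2ox\d*"),
    CandidateRule("GA metabolism", "GID1", r"gibberellin receptor|\bGID1\b"),
    CandidateRule("ABA metabolism", "CYP707A", r"abscisic acid 8'?-hydroxylase|\bCYP707A\d*"),
    CandidateRule("ABA metabolism", "GT", r"glucosyltransferase", "glucosyltransferase"),
    CandidateRule(
        "ABA metabolism", "beta-Glu", r"beta-glucosidase|β-glucosidase", "beta-glucosidase"
    ),
    CandidateRule("ABA metabolism", "PP2C", r"protein phosphatase 2C|\bPP2C\b"),
    CandidateRule("ABA metabolism", "ABI1", r"\bABI1\b"),
    CandidateRule("ABA metabolism", "ABI5", r"\bABI5\b"),
    CandidateRule("Ca transport", "TPC", r"two-pore (?:calcium )?channel|\bTPC\d*", "two-pore channel"),
    CandidateRule("Ca transport", "CAX", r"(?:Ca2?\+?/H\+?|cation/proton) exchanger|\bCAX\d*"),
    CandidateRule(
        "Ca transport", "Ca-ATPase", r"Ca2?\+?-ATPase|calcium-transporting ATPase", "Ca2+-ATPase"
    ),
    CandidateRule(
        "Ca transport", "CDPK", r"calcium-dependent protein kinase|\bCDPK\d*|\bCPK\d+"
    ),
    CandidateRule("Ca transport", "CBL", r"calcineurin B-like|\bCBL\d*"),
    CandidateRule("cell wall metabolism", "PG", r"polygalacturonase|\bPG\b", "polygalacturonase"),
    CandidateRule("cell wall metabolism", "EG", r"endoglucanase|\bcellulase|\bEG\b", "endoglucanase"),
    CandidateRule("cell wall metabolism", "PE", r"pectin ?esterase|pectinesterase", "pectinesterase"),
    CandidateRule("cell wall metabolism", "EXP", r"expansin|\bEXP[AB]?\d*", "expansin"),
    CandidateRule(
        "cell wall metabolism", "beta-Gal", r"beta-galactosidase|β-galactosidase", "beta-galactosidase"
    ),
    CandidateRule(
        "cell wall metabolism",
        "XET",
        r"xyloglucan endotransgl[uy]cosylase|\bXET\d*|\bXTH\d*",
        "xyloglucan endotransglycosylase",
    ),
)

HitsLike = Union[pd.DataFrame, Iterable[AnnotationHit]]
HIT_COLUMNS = ("unigene_id", "database", "description", "e_value")


def _hits_frame(hits: HitsLike) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
        df.columns = list(HIT_COLUMNS)[: df.shape[1]]
    else:
        df = pd.DataFrame(
            [(h.unigene_id, h.database, h.description, h.e_value) for h in hits],
            columns=list(HIT_COLUMNS),
        )
    df["e_value"] = df["e_value"].astype(float)
    return df


def filter_hits(hits: HitsLike, e_value_max: float = DEFAULT_EVALUE_MAX) -> pd.DataFrame:
    """Keep hits with E-value strictly below the cutoff."""
    df = _hits_frame(hits)
    return df[df["e_value"] < e_value_max].reset_index(drop=True)


def merge_annotations(
    hits: HitsLike, priority: Sequence[str] = DEFAULT_PRIORITY
) -> pd.DataFrame:
    """Adopt one description per unigene by database priority.

    Within the highest-priority database holding any hit for a unigene the
    best (lowest) E-value hit wins; remaining ties break on description
    then database so the result is independent of input order.

    Returns a DataFrame ``unigene_id, source_db, description, e_value``
    sorted by unigene_id, one row per annotated unigene.
    """
    df = _hits_frame(hits)
    unknown = set(df["database"]) - set(priority)
    if unknown:
        raise ValueError(f"hits from database(s) not in priority list: {sorted(unknown)}")
    if df.empty:
        return pd.DataFrame(columns=["unigene_id", "source_db", "description", "e_value"])
    rank = {db: k for k, db in enumerate(priority)}
    df = df.assign(_rank=df["database"].map(rank))
    df = df.sort_values(
        ["unigene_id", "_rank", "e_value", "description", "database"], kind="mergesort"
    )
    best = df.drop_duplicates("unigene_id", keep="first")
    return (
        best.rename(columns={"database": "source_db"})[
            ["unigene_id", "source_db", "description", "e_value"]
        ].reset_index(drop=True)
    )


def summarize_hits(hits: HitsLike, total_unigenes: int) -> pd.DataFrame:
    """Per-database distinct-unigene hit counts and percentages.

    Adds an ``any`` row counting unigenes hit in at least one database.
    Percentages are of ``total_unigenes``, half-up to 2 decimals.
    """
    df = _hits_frame(hits)
    counts = {db: int(df.loc[df["database"] == db, "unigene_id"].nunique()) for db in
              dict.fromkeys(df["database"])}
    counts["any"] = int(df["unigene_id"].nunique())
    return summarize_hit_counts(counts, total_unigenes)


def summarize_hit_counts(counts: Mapping[str, int], total_unigenes: int) -> pd.DataFrame:
    """Summary table from precomputed per-database distinct-unigene counts."""
    if total_unigenes <= 0:
        raise ValueError(f"total_unigenes must be positive, got {total_unigenes}")
    bad = [db for db, c in counts.items() if c > total_unigenes]
    if bad:
        raise ValueError(f"hit count exceeds total_unigenes for: {bad}")
    rows = [(db, int(c), percent_of(int(c), total_unigenes)) for db, c in counts.items()]
    return pd.DataFrame(rows, columns=["database", "n_hits", "percent"])


def summarize_categories(
    assignments: Iterable[tuple[str, str]], base: str = "classified"
) -> pd.DataFrame:
    """Category counts and percentages from (unigene_id, category) pairs.

    ``base='classified'`` divides by the number of distinct classified
    unigenes (the COG/KEGG convention: a unigene in several categories is
    counted once in the base, so percentages may sum past 100);
    ``base='assignments'`` divides by the number of assignment pairs.
    Sorted by descending count, stable on ties.
    """
    pairs = list(assignments)
    if not pairs:
        raise ValueError("no category assignments given")
    if base not in ("classified", "assignments"):
        raise ValueError(f"base must be 'classified' or 'assignments', got {base!r}")
    df = pd.DataFrame(pairs, columns=["unigene_id", "category"])
    denom = df["unigene_id"].nunique() if base == "classified" else len(df)
    counts = df.groupby("category", sort=False)["unigene_id"].count()
    out = pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.to_numpy(dtype=int),
        }
    )
    out["percent"] = [percent_of(c, denom) for c in out["count"]]
    return out.sort_values("count", ascending=False, kind="mergesort").reset_index(drop=True)


def classify_candidates(
    deg_results: pd.DataFrame,
    merged: pd.DataFrame,
    rules: Sequence[CandidateRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Assign DEGs to candidate pathways by ordered keyword rules.

    Only rows with ``is_deg`` are considered; each DEG whose adopted
    description matches at least one rule pattern is assigned to the first
    matching rule; DEGs without a match (or without an annotation) are
    omitted. Returns ``pathway, family_label, unigene_id, direction,
    log2fc`` in rule order then input order.
    """
    seen = set()
    for r in rules:
        key = (r.pathway, r.family_label)
        if key in seen:
            raise ValueError(f"duplicate rule for {key}")
        seen.add(key)
    compiled = [(r, r.regex) for r in rules]

    degs = deg_results[deg_results["is_deg"]]
    desc = dict(zip(merged["unigene_id"], merged["description"]))
    rows = []
    for _, row in degs.iterrows():
        d = desc.get(row["unigene_id"])
        if d is None:
            continue
        for r, rx in compiled:
            if rx.search(d):
                rows.append(
                    (r.pathway, r.family_label, row["unigene_id"], row["direction"], row["log2fc"])
                )
                break
    out = pd.DataFrame(
        rows, columns=["pathway", "family_label", "unigene_id", "direction", "log2fc"]
    )
    order = {(r.pathway, r.family_label): k for k, r in enumerate(rules)}
    if not out.empty:
        out = (
            out.assign(_k=[order[(p, f)] for p, f in zip(out["pathway"], out["family_label"])])
            .sort_values("_k", kind="mergesort")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
    return out
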