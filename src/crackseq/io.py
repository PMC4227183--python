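"""Readers and writers for the pipeline's TSV and FASTA interfaces.

All tables are UTF-8, tab-separated, LF line endings, with a mandatory
header; ``#``-prefixed comment lines are skipped. Writers and readers
round-trip field-for-field.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import CandidateRule
from .count_model import UnigeneRecord

__all__ = [
    "read_table",
    "write_table",
    "read_count_table",
    "write_count_table",
    "read_lengths",
    "write_lengths",
    "read_hits",
    "write_hits",
    "read_rules",
    "write_rules",
    "read_deg_results",
    "write_deg_results",
    "read_fasta",
    "write_fasta",
]

COUNT_HEADER = ["unigene_id", "count_sample1", "count_sample2"]
LENGTH_HEADER = ["unigene_id", "length_bp"]
HIT_HEADER = ["unigene_id", "database", "description", "e_value"]
RULE_HEADER = ["pathway", "family_label", "pattern"]
DEG_HEADER = [
    "unigene_id", "rpkm_sample1", "rpkm_sample2", "log2fc", "p_value", "fdr", "is_deg", "direction",
]


def read_table(path, expected_header: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    got = list(df.columns)
    if got != list(expected_header):
        raise ValueError(f"{path}: expected header {list(expected_header)}, got {got}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_count_table(path) -> pd.DataFrame:
    """Count TSV -> DataFrame ``unigene_id, count_1, count_2`` (int)."""
    df = read_table(path, COUNT_HEADER)
    return pd.DataFrame(
        {
            "unigene_id": df["unigene_id"],
            "count_1": df["count_sample1"].astype(int),
            "count_2": df["count_sample2"].astype(int),
        }
    )


def write_count_table(counts: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "unigene_id": counts.iloc[:, 0],
            "count_sample1": counts.iloc[:, 1].astype(int),
            "count_sample2": counts.iloc[:, 2].astype(int),
        }
    )
    write_table(out, path)


def read_lengths(path) -> pd.Series:
    df = read_table(path, LENGTH_HEADER)
    s = pd.Series(
        df["length_bp"].astype(int).to_numpy(),
        index=pd.Index(df["unigene_id"], name="unigene_id"),
        name="length_bp",
    )
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate unigene_id {dup!r}")
    return s


def write_lengths(lengths: pd.Series, path) -> None:
    out = pd.DataFrame({"unigene_id": lengths.index, "length_bp": lengths.astype(int).to_numpy()})
    write_table(out, path)


def read_hits(path) -> pd.DataFrame:
    df = read_table(path, HIT_HEADER)
    df["e_value"] = df["e_value"].astype(float)
    return df


def write_hits(hits: pd.DataFrame, path) -> None:
    out = hits.copy()
    out["e_value"] = [format(v, ".6g") for v in out["e_value"].astype(float)]
    write_table(out[HIT_HEADER], path)


def read_rules(path) -> list[CandidateRule]:
    """Rules TSV (order significant) -> list of CandidateRule."""
    df = read_table(path, RULE_HEADER)
    return [CandidateRule(p, f, rx) for p, f, rx in df.itertuples(index=False)]


def write_rules(rules: Iterable[CandidateRule], path) -> None:
    out = pd.DataFrame(
        [(r.pathway, r.family_label, r.pattern) for r in rules], columns=RULE_HEADER
    )
    write_table(out, path)


def write_deg_results(results: pd.DataFrame, path) -> None:
    """DEG result TSV: floats at 6 significant digits, booleans true/false."""
    out = pd.DataFrame(
        {
            "unigene_id": results["unigene_id"],
            "rpkm_sample1": [format(v, ".6g") for v in results["rpkm_1"]],
            "rpkm_sample2": [format(v, ".6g") for v in results["rpkm_2"]],
            "log2fc": [format(v, ".6g") for v in results["log2fc"]],
            "p_value": [format(v, ".6g") for v in results["p_value"]],
            "fdr": [format(v, ".6g") for v in results["fdr"]],
            "is_deg": ["true" if b else "false" for b in results["is_deg"]],
            "direction": results["direction"],
        }
    )
    write_table(out, path)


def read_deg_results(path) -> pd.DataFrame:
    df = read_table(path, DEG_HEADER)
    return pd.DataFrame(
        {
            "unigene_id": df["unigene_id"],
            "rpkm_1": df["rpkm_sample1"].astype(float),
            "rpkm_2": df["rpkm_sample2"].astype(float),
            "log2fc": df["log2fc"].astype(float),
            "p_value": df["p_value"].astype(float),
            "fdr": df["fdr"].astype(float),
            "is_deg": df["is_deg"].map({"true": True, "false": False}),
            "direction": df["direction"],
        }
    )


def read_fasta(path) -> list[UnigeneRecord]:
    """FASTA -> UnigeneRecords; ids are the first header token, sequences
    uppercased; duplicate ids, non-ACGTN characters or an empty file are
    errors."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        uid = rec.id
        if uid in seen:
            raise ValueError(f"{path}: duplicate FASTA id {uid!r}")
        seen.add(uid)
        seq = str(rec.seq).upper()
        records.append(UnigeneRecord(uid, len(seq), seq))  # validates alphabet
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[UnigeneRecord], path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence or "N" * r.length_bp), id=r.unigene_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
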