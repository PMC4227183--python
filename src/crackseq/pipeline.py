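"""Whole-pipeline driver: summarize -> deg -> annotate -> candidates.

A :class:`RunConfig` names the inputs (FASTA, count table, optional hit and
rule tables), the library metadata and thresholds; :func:`run_pipeline`
executes every stage in order, writes all output tables plus a JSON
manifest (config, input checksums, package version), and removes partial
outputs if any stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotation import (
    DEFAULT_EVALUE_MAX,
    DEFAULT_PRIORITY,
    classify_candidates,
    filter_hits,
    merge_annotations,
    summarize_hits,
)
from .count_model import LibraryPair
from .expression import DegThresholds, call_degs, partition_degs
from .io import (
    read_count_table,
    read_fasta,
    read_hits,
    read_rules,
    write_deg_results,
    write_table,
)
from .summaries import assembly_stats

logger = logging.getLogger("crackseq")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs, outputs and parameters of a full pipeline run."""

    fasta: Path
    counts: Path
    out_dir: Path
    label_1: str = "sample1"
    label_2: str = "sample2"
    n1: Optional[int] = None  #: default: column sum of the count table
    n2: Optional[int] = None
    hits: Optional[Path] = None
    rules: Optional[Path] = None
    fdr_max: float = 0.001
    min_abs_log2fc: float = 1.0
    zero_substitute: float = 0.001
    min_length_bp: int = 200
    priority: Sequence[str] = DEFAULT_PRIORITY
    e_value_max: float = DEFAULT_EVALUE_MAX
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Outputs in ``config.out_dir``: ``summary.tsv``, ``deg_results.tsv``,
    and when hit/rule tables are given ``merged.tsv``, ``hit_summary.tsv``,
    ``candidates.tsv``; always ``manifest.json``. On any stage error the
    partially written outputs are removed and the error re-raised with the
    stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _write(name: str, writer, *args) -> Path:
        path = out_dir / name
        writer(*args, path)
        written.append(path)
        return path

    try:
        stage = "summarize"
        records = read_fasta(config.fasta)
        summary = assembly_stats(records, min_length_bp=config.min_length_bp)
        logger.info("summarize: %d unigenes, mean %d bp", summary.n_sequences, summary.mean_length_bp)
        srows = [
            ("n_unigenes", summary.n_sequences),
            ("total_length_bp", summary.total_length_bp),
            ("mean_length_bp", summary.mean_length_bp),
            ("n50_bp", summary.n50_bp),
        ]
        _write("summary.tsv", write_table, pd.DataFrame(srows, columns=["statistic", "value"]))

        stage = "deg"
        counts = read_count_table(config.counts)
        n1 = config.n1 if config.n1 is not None else int(counts["count_1"].sum())
        n2 = config.n2 if config.n2 is not None else int(counts["count_2"].sum())
        pair = LibraryPair(config.label_1, config.label_2, n1, n2)
        lengths = {r.unigene_id: r.length_bp for r in records}
        thresholds = DegThresholds(config.fdr_max, config.min_abs_log2fc, config.zero_substitute)
        results = call_degs(counts, lengths, pair, thresholds)
        n_up, n_down, n_total = partition_degs(results)
        logger.info("deg: %d DEGs (%d up, %d down) of %d unigenes", n_total, n_up, n_down, len(results))
        _write("deg_results.tsv", write_deg_results, results)

        merged = None
        if config.hits is not None:
            stage = "annotate"
            hits = filter_hits(read_hits(config.hits), config.e_value_max)
            merged = merge_annotations(hits, config.priority)
            logger.info("annotate: %d unigenes annotated", len(merged))
            _write("merged.tsv", write_table, merged)
            _write("hit_summary.tsv", write_table, summarize_hits(hits, len(records)))

        if config.rules is not None:
            stage = "candidates"
            if merged is None:
                raise ValueError("candidate classification requires a hits table")
            rules = read_rules(config.rules)
            cands = classify_candidates(results, merged, rules)
            logger.info("candidates: %d DEGs classified", len(cands))
            _write("candidates.tsv", write_table, cands)

        stage = "manifest"
        manifest = {
            "tool": "crackseq",
            "version": __version__,
            "config": {
                k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "library_totals": {"n1": n1, "n2": n2},
            "inputs": {
                str(p): _sha256(Path(p))
                for p in [config.fasta, config.counts, config.hits, config.rules]
                if p is not None
            },
            "outputs": [p.name for p in written],
            "deg_counts": {"up": n_up, "down": n_down, "total": n_total},
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
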