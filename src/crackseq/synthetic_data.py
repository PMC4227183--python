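"""Synthetic two-library count data, unigenes and annotations.

The generator emulates the study design the pipeline targets: two pooled
sequencing libraries (no replicates), per-gene relative abundances drawn
log-normal, a chosen fraction of genes truly differential at a fixed fold
change (alternating up/down so both directions occur), and Poisson count
noise. Poisson — not negative binomial — because the pipeline's
significance formula is exact under Poisson sampling of a single library
pair; overdispersion would test a model the design does not use.

Default depths and length range mirror a real litchi pericarp experiment
(~25.9M and ~29.4M mapped reads, ~950 bp mean unigene length); tests use
smaller depths for speed. All generators are deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CandidateRule, DEFAULT_RULES
from .count_model import LibraryPair, UnigeneRecord

__all__ = ["SimulationConfig", "simulate_counts", "simulate_annotations", "simulate_unigenes"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the two-library simulation; defaults mirror the target study."""

    n_genes: int = 46_641
    depth_1: int = 25_867_380
    depth_2: int = 29_444_512
    de_fraction: float = 0.05
    fold_change: float = 4.0
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.0
    length_min_bp: int = 200
    length_max_bp: int = 1_700
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.depth_1 < 1 or self.depth_2 < 1:
            raise ValueError("library depths must be >= 1")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if not (1 <= self.length_min_bp <= self.length_max_bp):
            raise ValueError("need 1 <= length_min_bp <= length_max_bp")


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"Unigene_{k + 1:0{width}d}" for k in range(n)]


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, LibraryPair, pd.Series, pd.DataFrame]:
    """Draw one two-library count table plus ground truth.

    Per gene g a relative abundance a_g ~ LogNormal(mu, sigma). A
    ``de_fraction`` of genes (chosen at random) have their library-2
    abundance multiplied by ``fold_change`` or its reciprocal, alternating
    so half go up and half down. Expected counts are depth_k times the
    renormalized abundances; observed counts are Poisson draws. Lengths
    are uniform integers in [length_min_bp, length_max_bp].

    Returns ``(counts, pair, lengths, truth)``: the count table DataFrame,
    the :class:`LibraryPair` (totals = configured depths), a Series of
    lengths indexed by unigene_id, and the truth table with columns
    ``unigene_id, is_de, true_log2fc``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    ids = _gene_ids(n)

    a1 = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n)
    n_de = int(round(config.de_fraction * n))
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    mult = np.ones(n)
    # alternate up/down over the DE genes so both directions are exercised
    for k, g in enumerate(de_idx):
        mult[g] = config.fold_change if k % 2 == 0 else 1.0 / config.fold_change
    a2 = a1 * mult

    lam1 = config.depth_1 * a1 / a1.sum()
    lam2 = config.depth_2 * a2 / a2.sum()
    x = rng.poisson(lam1)
    i = rng.poisson(lam2)

    lengths = rng.integers(config.length_min_bp, config.length_max_bp + 1, n)

    counts = pd.DataFrame({"unigene_id": ids, "count_1": x, "count_2": i})
    pair = LibraryPair("sample1", "sample2", config.depth_1, config.depth_2)
    truth = pd.DataFrame(
        {
            "unigene_id": ids,
            "is_de": mult != 1.0,
            "true_log2fc": np.where(mult != 1.0, np.log2(mult), 0.0),
        }
    )
    return counts, pair, pd.Series(lengths, index=pd.Index(ids, name="unigene_id"), name="length_bp"), truth


#: Generic descriptions for non-candidate genes; none matches a default rule.
_GENERIC_DESCRIPTIONS = (
    "hypothetical protein",
    "uncharacterized protein",
    "40S ribosomal protein S{k}",
    "heat shock protein {k} kDa",
    "ubiquitin-conjugating enzyme E2 {k}",
    "serine/threonine-protein kinase {k}",
    "pentatricopeptide repeat-containing protein {k}",
    "zinc finger protein {k}",
)


def simulate_annotations(
    truth: pd.DataFrame,
    rules: Sequence[CandidateRule] = DEFAULT_RULES,
    candidate_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic NR annotation hits for the simulated genes.

    A ``candidate_fraction`` of the truly differential genes receive
    descriptions embedding the example keyword of a randomly chosen rule;
    all other genes get generic descriptions free of rule keywords.
    E-values are drawn log-uniform in [1e-50, 1e-6], below the usual 1e-5
    cutoff. Returns a hit table ``unigene_id, database, description,
    e_value``.
    """
    if not (0.0 <= candidate_fraction <= 1.0):
        raise ValueError("candidate_fraction must lie in [0, 1]")
    if not rules:
        raise ValueError("need at least one rule")
    keyed = [r for r in rules if r.example]
    if not keyed:
        raise ValueError("no rule has a usable example keyword")
    rng = np.random.default_rng(seed)

    ids = truth["unigene_id"].tolist()
    is_de = truth["is_de"].to_numpy(dtype=bool)
    de_ids = [uid for uid, d in zip(ids, is_de) if d]
    n_cand = int(round(candidate_fraction * len(de_ids)))
    cand = set(rng.choice(de_ids, size=n_cand, replace=False)) if n_cand else set()

    rows = []
    for uid in ids:
        if uid in cand:
            rule = keyed[rng.integers(0, len(keyed))]
            desc = f"{rule.example} family protein, putative"
        else:
            tmpl = _GENERIC_DESCRIPTIONS[rng.integers(0, len(_GENERIC_DESCRIPTIONS))]
            desc = tmpl.format(k=int(rng.integers(1, 100)))
        e_value = 10.0 ** rng.uniform(-50, -6)
        rows.append((uid, "NR", desc, e_value))
    return pd.DataFrame(rows, columns=["unigene_id", "database", "description", "e_value"])


def simulate_unigenes(lengths, seed: int = 0) -> list[UnigeneRecord]:
    """Uniform-random A/C/G/T sequences of the given lengths.

    ``lengths`` may be a Series indexed by unigene_id or a plain sequence
    (ids are then generated).
    """
    rng = np.random.default_rng(seed)
    if isinstance(lengths, pd.Series):
        items = list(lengths.items())
    else:
        lens = list(lengths)
        items = list(zip(_gene_ids(len(lens)), lens))
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    out = []
    for uid, L in items:
        L = int(L)
        if L < 1:
            raise ValueError(f"{uid}: length must be >= 1")
        seq = rng.choice(alphabet, size=L).tobytes().decode("ascii")
        out.append(UnigeneRecord(str(uid), L, seq))
    return out
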