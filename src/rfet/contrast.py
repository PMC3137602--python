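"""Contrastive filtering of two top-K gene lists.

Genes appearing in the top-K lists of both phenotype-group runs ("tuning
genes" — generic responders rather than trait-specific ones) are identified
by exact set intersection on probe ids and removed from the target list,
which keeps its original order and is re-ranked 1..m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._errors import ConfigError, DataError

__all__ = ["TuningGene", "TuningGeneReport", "find_tuning_genes", "overlap_count"]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class TuningGene:
    probe_id: str
    rank_in_a: int
    rank_in_b: int


@dataclass
class TuningGeneReport:
    list_a_top: list[str]
    list_b_top: list[str]
    tuning_genes: list[TuningGene]  # ordered by rank in list A
    cleaned_list: list[str]  # list A top-K minus tuning genes, order kept

    @property
    def tuning_ids(self) -> set[str]:
        return {t.probe_id for t in self.tuning_genes}

    def cleaned_ranks(self) -> dict[str, int]:
        return {p: i + 1 for i, p in enumerate(self.cleaned_list)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"probe_id": t.probe_id, "status": "tuning", "rank_in_a": t.rank_in_a, "rank_in_b": t.rank_in_b}
            for t in self.tuning_genes
        ] + [
            {"probe_id": p, "status": "kept", "rank_in_a": self.list_a_top.index(p) + 1, "rank_in_b": ""}
            for p in self.cleaned_list
        ]
        return pd.DataFrame(rows, columns=["probe_id", "status", "rank_in_a", "rank_in_b"])


def _validated_topk(probes: Sequence[str], K: int, name: str) -> list[str]:
    if K < 1:
        raise ConfigError(f"K must be >= 1, got {K}")
    if len(probes) < K:
        raise ConfigError(f"K={K} exceeds {name} length {len(probes)}")
    dups = {p for p in probes if list(probes).count(p) > 1}
    if dups:
        raise DataError(f"duplicate probe(s) in {name}: {sorted(dups)}")
    return list(probes[:K])


def find_tuning_genes(list_a: Sequence[str], list_b: Sequence[str], K: int) -> TuningGeneReport:
    """Intersect the top-K prefixes of two ordered probe lists.

    The cleaned list is list A's top-K with the shared genes removed,
    original order preserved.
    """
    top_a = _validated_topk(list_a, K, "list A")
    top_b = _validated_topk(list_b, K, "list B")
    set_b = set(top_b)
    tuning = [
        TuningGene(p, rank_in_a=i + 1, rank_in_b=top_b.index(p) + 1)
        for i, p in enumerate(top_a)
        if p in set_b
    ]
    tuning_ids = {t.probe_id for t in tuning}
    cleaned = [p for p in top_a if p not in tuning_ids]
    return TuningGeneReport(top_a, top_b, tuning, cleaned)


def overlap_count(list_a: Sequence[str], list_b: Sequence[str], K: int) -> int:
    """|top-K(A) ∩ top-K(B)| on probe ids."""
    top_a = _validated_topk(list_a, K, "list A")
    top_b = _validated_topk(list_b, K, "list B")
    return len(set(top_a) & set(top_b))


def _load_bundled(name: str) -> list[str]:
    path = _DATA_DIR / name
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [str(p) for p in df["probe_id"]]


def bundled_resistant_top10() -> list[str]:
    """Bundled example: top-10 list from the drought-tolerant genotype run."""
    return _load_bundled("demo_resistant_top10.tsv")


def bundled_susceptible_top10() -> list[str]:
    """Bundled example: top-10 list from the drought-susceptible genotype run."""
    return _load_bundled("demo_susceptible_top10.tsv")


def bundled_cleaned_top7() -> list[str]:
    """Bundled example: the resistant list after tuning-gene removal."""
    return _load_bundled("demo_cleaned_top7.tsv")
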