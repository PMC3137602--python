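"""Synthetic log-scale expression matrices with planted class signal.

Null genes are Normal(baseline, noise_sd^2) identically in both classes;
informative genes are shifted upward by effect_size * noise_sd in class 1.
Optional equicorrelated blocks among the null genes model co-expression.
Everything is reproducible from the spec seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._errors import ConfigError, DataError
from .ensemble import aggregate_rankings, make_cv_plan, run_ensemble
from .io_core import ExpressionMatrix, SampleRecord, SampleTable
from .prefilter import filter_by_pvalue, ttest_per_gene
from .svm_rfe import SVMConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "PipelineConfig",
    "RecoveryReport",
    "simulate",
    "run_pipeline_on",
    "recovery_experiment",
    "max_topn_occurrence",
    "permutation_null_max_occurrence",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 736
    n_samples_per_class: int = 6
    n_informative: int = 5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    block_correlation: float = 0.0
    block_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_samples_per_class < 2:
            raise ConfigError("n_samples_per_class must be >= 2")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ConfigError("n_informative must be in [0, n_genes]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not (0 <= self.block_correlation < 1):
            raise ConfigError("block_correlation must be in [0, 1)")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")


def simulate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SampleTable, list[str]]:
    """Generate (matrix, samples, informative probe ids) from the spec.

    Probes ``g0001`` .. are ordered with the informative genes first;
    samples interleave class 1 ("wet") and class 0 ("dry") replicates.
    """
    rng = np.random.default_rng(spec.seed)
    g, npc = spec.n_genes, spec.n_samples_per_class
    n = 2 * npc
    width = max(4, len(str(g)))
    probe_ids = [f"g{i + 1:0{width}d}" for i in range(g)]
    informative = probe_ids[: spec.n_informative]

    noise = rng.normal(0.0, 1.0, size=(g, n))
    if spec.block_correlation > 0:
        # equicorrelated blocks among null genes via a shared block factor
        rho = spec.block_correlation
        null_rows = np.arange(spec.n_informative, g)
        n_blocks = int(np.ceil(len(null_rows) / spec.block_size))
        factors = rng.normal(0.0, 1.0, size=(n_blocks, n))
        for b in range(n_blocks):
            rows = null_rows[b * spec.block_size : (b + 1) * spec.block_size]
            noise[rows] = np.sqrt(rho) * factors[b] + np.sqrt(1 - rho) * noise[rows]
    values = spec.baseline + spec.noise_sd * noise

    labels = np.tile([1, 0], npc)  # wet/dry alternating, like paired replicates
    shift = spec.effect_size * spec.noise_sd
    for i in range(spec.n_informative):
        values[i, labels == 1] += shift

    records = []
    for j in range(n):
        records.append(
            SampleRecord(
                sample_id=f"S{j + 1:02d}",
                group="sim",
                condition="well watered" if labels[j] == 1 else "drought",
                replicate=j // 2 + 1,
                class_label=int(labels[j]),
            )
        )
    matrix = ExpressionMatrix(probe_ids, [r.sample_id for r in records], values)
    return matrix, SampleTable(records), informative


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the filter -> ensemble -> aggregate pipeline."""

    alpha: float = 0.05
    t_variant: str = "pooled"
    n_folds: int = 6
    repetitions: int = 20
    top_n: int = 10
    mode: str = "per_repetition"
    stratified: bool = False
    svm: SVMConfig = SVMConfig()
    seed: int = 0


def run_pipeline_on(matrix: ExpressionMatrix, labels: np.ndarray, config: PipelineConfig):
    """filter -> ensemble -> aggregate on an in-memory matrix.

    Returns (aggregate, lists, accuracies, filtered_probes).
    """
    results = ttest_per_gene(matrix, labels, variant=config.t_variant)
    kept = filter_by_pvalue(results, config.alpha)
    if len(kept) < 2:
        raise DataError(f"only {len(kept)} gene(s) passed the filter at alpha={config.alpha}")
    sub = matrix.subset_probes(kept)
    plan = make_cv_plan(
        sub.n_samples,
        config.n_folds,
        config.repetitions,
        config.seed,
        labels=labels,
        stratified=config.stratified,
    )
    lists, accuracies = run_ensemble(sub, labels, plan, config.svm, mode=config.mode)
    n_eff = min(config.top_n, min(len(l) for l in lists))
    if n_eff < config.top_n:
        logger.info("top_n reduced to %d (filtered universe smaller than requested N)", n_eff)
    agg = aggregate_rankings(lists, N=n_eff)
    return agg, lists, accuracies, kept


def max_topn_occurrence(matrix: ExpressionMatrix, labels: np.ndarray, config: PipelineConfig) -> int:
    """Largest top-N occurrence any gene attains across the ensemble lists."""
    _, lists, _, _ = run_pipeline_on(matrix, labels, config)
    n_eff = min(config.top_n, min(len(l) for l in lists))
    counts: dict[str, int] = {}
    for fl in lists:
        for probe, rank in fl.ranks().items():
            if rank <= n_eff:
                counts[probe] = counts.get(probe, 0) + 1
    return max(counts.values()) if counts else 0


def permutation_null_max_occurrence(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    config: PipelineConfig,
    n_permutations: int,
    seed: int,
) -> list[int]:
    """Null distribution of the max top-N occurrence under label shuffling.

    Each permutation reruns the full filter -> ensemble pipeline on the
    shuffled labels (per-permutation pipeline seeds derive from ``seed``).
    """
    rng = np.random.default_rng(seed)
    out = []
    for b in range(n_permutations):
        perm = rng.permutation(np.asarray(labels))
        cfg_b = replace(config, seed=config.seed + 1 + b)
        out.append(max_topn_occurrence(matrix, perm, cfg_b))
    return out


@dataclass
class RecoveryReport:
    informative: list[str]
    passed_filter: list[str]
    final_ranks: dict[str, int]  # planted gene -> final rank (0 = filtered out)
    top_n_occurrence: dict[str, int]  # planted gene -> ensemble top-N occurrence
    max_null_occurrence: int
    mean_heldout_accuracy: float

    def planted_in_top(self, K: int) -> bool:
        return all(0 < r <= K for r in self.final_ranks.values())


def recovery_experiment(spec: SyntheticSpec, config: PipelineConfig) -> RecoveryReport:
    """Simulate, run the full pipeline, and report where the truth landed."""
    matrix, samples, informative = simulate(spec)
    labels = samples.class_labels
    agg, lists, accuracies, kept = run_pipeline_on(matrix, labels, config)
    final_ranks = agg.final_ranks()
    planted_ranks = {p: final_ranks.get(p, 0) for p in informative}
    rank_maps = [fl.ranks() for fl in lists]
    counts: dict[str, int] = {}
    for rm in rank_maps:
        for probe, rank in rm.items():
            if rank <= agg.top_n:
                counts[probe] = counts.get(probe, 0) + 1
    occ = {p: counts.get(p, 0) for p in informative}
    planted = set(informative)
    null_occ = [c for probe, c in counts.items() if probe not in planted]
    return RecoveryReport(
        informative=informative,
        passed_filter=kept,
        final_ranks=planted_ranks,
        top_n_occurrence=occ,
        max_null_occurrence=max(null_occ) if null_occ else 0,
        mean_heldout_accuracy=float(np.mean([a.accuracy for a in accuracies])),
    )
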