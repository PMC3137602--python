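"""Repeated n-fold subset-leave-out resampling of SVM-RFE and the
occurrence/rank/weight re-ranking aggregation into one final gene list.

A "repetition" randomly partitions the samples into ``n_folds`` near-equal
subsets; each fold's training set is all samples minus one subset, and one
RFE ranking is produced per fold. In ``per_repetition`` mode (default) the
fold-level rankings of a repetition are merged into one list by mean rank,
so ``repetitions`` lists reach the aggregation stage; ``pooled`` mode keeps
every fold-level list.

The aggregate score for gene j over p lists with top-N gating is

    O_j     = #{k : rank_jk <= N}
    score_j = sum over those k of  w_jk * (N - rank_jk + 1) / N

where w_jk is the squared-weight criterion recorded when the gene was
eliminated in list k. Genes never inside any top-N score 0 and are ordered
after all scored genes by mean rank. The scoring lives in a single function
(:func:`composite_score`) so an alternative algebra can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigError, DataError
from .io_core import ExpressionMatrix, RankedEntry, RankedList
from .svm_rfe import SVMConfig, encode_labels, standardize_features, svm_rfe_rank, train_linear_svm

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "FoldAccuracy",
    "AggregateEntry",
    "AggregateRanking",
    "make_cv_plan",
    "run_ensemble",
    "merge_fold_lists",
    "composite_score",
    "aggregate_rankings",
    "top_n_occurrence",
    "occurrence_table",
]


@dataclass
class CVPlan:
    """Resampling plan: per repetition, a partition into near-equal subsets."""

    n_samples: int
    n_folds: int
    repetitions: int
    seed: int
    splits: list[list[np.ndarray]]  # [repetition][fold] -> held-out sample indices

    def __post_init__(self) -> None:
        for rep, folds in enumerate(self.splits):
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise DataError(f"repetition {rep}: fold sizes {sizes} differ by more than 1")
            all_idx = np.sort(np.concatenate(folds))
            if not np.array_equal(all_idx, np.arange(self.n_samples)):
                raise DataError(f"repetition {rep}: folds do not partition the samples")


def make_cv_plan(
    n_samples: int,
    n_folds: int,
    repetitions: int,
    seed: int,
    labels: np.ndarray | None = None,
    stratified: bool = False,
) -> CVPlan:
    """Build a reproducible plan of ``repetitions`` random n-fold partitions."""
    if n_folds < 2:
        raise ConfigError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > n_samples:
        raise ConfigError(f"n_folds ({n_folds}) exceeds n_samples ({n_samples})")
    if repetitions < 1:
        raise ConfigError(f"repetitions must be >= 1, got {repetitions}")
    if stratified and labels is None:
        raise ConfigError("stratified splitting requires labels")
    rng = np.random.default_rng(seed)
    splits: list[list[np.ndarray]] = []
    for _ in range(repetitions):
        if stratified:
            folds: list[list[int]] = [[] for _ in range(n_folds)]
            pos = 0  # rotating fold pointer keeps sizes within 1
            for cls in (0, 1):
                members = np.flatnonzero(np.asarray(labels) == cls)
                for idx in rng.permutation(members):
                    folds[pos % n_folds].append(int(idx))
                    pos += 1
            splits.append([np.sort(np.array(f, dtype=int)) for f in folds])
        else:
            perm = rng.permutation(n_samples)
            splits.append([np.sort(f) for f in np.array_split(perm, n_folds)])
    return CVPlan(n_samples, n_folds, repetitions, seed, splits)


@dataclass
class FoldAccuracy:
    repetition: int
    fold: int
    n_heldout: int
    accuracy: float


def merge_fold_lists(fold_lists: list[RankedList], probe_order: list[str]) -> RankedList:
    """Merge one repetition's fold-level rankings by mean rank.

    Ordering: mean rank ascending, ties by mean criterion descending, then
    by position in ``probe_order`` (the input matrix's probe order).
    """
    if not fold_lists:
        raise DataError("no fold lists to merge")
    probes = fold_lists[0].probe_ids
    if any(set(fl.probe_ids) != set(probes) for fl in fold_lists):
        raise DataError("fold lists rank different gene sets")
    pos = {p: i for i, p in enumerate(probe_order)}
    mean_rank = {p: 0.0 for p in probes}
    mean_crit = {p: 0.0 for p in probes}
    for fl in fold_lists:
        ranks = fl.ranks()
        crits = fl.criteria()
        for p in probes:
            mean_rank[p] += ranks[p]
            mean_crit[p] += crits[p]
    k = len(fold_lists)
    ordered = sorted(probes, key=lambda p: (mean_rank[p] / k, -mean_crit[p] / k, pos.get(p, len(pos))))
    g = len(ordered)
    entries = [
        RankedEntry(p, g - position, mean_crit[p] / k)  # position 0 (best) -> step g
        for position, p in enumerate(ordered)
    ]
    return RankedList(entries)


def run_ensemble(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    plan: CVPlan,
    svm_config: SVMConfig = SVMConfig(),
    mode: str = "per_repetition",
) -> tuple[list[RankedList], list[FoldAccuracy]]:
    """Run SVM-RFE on every (repetition, fold) training set.

    Returns the ranked lists (``repetitions`` of them in ``per_repetition``
    mode, ``repetitions * n_folds`` in ``pooled`` mode) and a held-out
    accuracy log from each fold's full-feature SVM. The accuracy log is
    reporting only and never feeds the ranking.
    """
    if mode not in ("per_repetition", "pooled"):
        raise ConfigError(f"unknown ensemble mode {mode!r}")
    labels = np.asarray(labels)
    if plan.n_samples != matrix.n_samples:
        raise DataError(
            f"plan covers {plan.n_samples} samples but matrix has {matrix.n_samples}"
        )
    X_all = matrix.values.T  # samples x genes
    lists: list[RankedList] = []
    accuracies: list[FoldAccuracy] = []
    for rep, folds in enumerate(plan.splits):
        fold_lists: list[RankedList] = []
        for fold, heldout in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(plan.n_samples), heldout)
            y_train = labels[train_idx]
            if len(np.unique(y_train)) < 2:
                raise DataError(
                    f"repetition {rep}, fold {fold}: training set is single-class; "
                    "regenerate the plan with a new seed or stratified=True"
                )
            sub = ExpressionMatrix(
                list(matrix.probe_ids),
                [matrix.sample_ids[i] for i in train_idx],
                matrix.values[:, train_idx],
            )
            fold_lists.append(svm_rfe_rank(sub, y_train, svm_config))

            # held-out evaluation with the full-feature model (reporting only)
            X_train = X_all[train_idx]
            X_test = X_all[heldout]
            if svm_config.standardize:
                mu = X_train.mean(axis=0)
                sd = X_train.std(axis=0, ddof=0)
                sd = np.where(sd == 0.0, 1.0, sd)
                X_train = (X_train - mu) / sd
                X_test = (X_test - mu) / sd
            model = train_linear_svm(X_train, y_train, C=svm_config.C, tol=svm_config.tol)
            acc = float(np.mean(model.predict(X_test) == labels[heldout]))
            accuracies.append(FoldAccuracy(rep, fold, len(heldout), acc))
        if mode == "per_repetition":
            lists.append(merge_fold_lists(fold_lists, list(matrix.probe_ids)))
        else:
            lists.extend(fold_lists)
        logger.debug("repetition %d/%d complete", rep + 1, plan.repetitions)
    return lists, accuracies


@dataclass
class AggregateEntry:
    probe_id: str
    occurrence: int  # O_j: lists where rank <= N
    weight_sum: float  # S_j: sum of criterion values over those lists
    score: float
    mean_rank: float
    final_rank: int


@dataclass
class AggregateRanking:
    n_lists: int
    top_n: int
    entries: list[AggregateEntry]

    def ordered_probes(self) -> list[str]:
        return [e.probe_id for e in self.entries]

    def final_ranks(self) -> dict[str, int]:
        return {e.probe_id: e.final_rank for e in self.entries}


def composite_score(ranks: np.ndarray, weights: np.ndarray, N: int) -> float:
    """Occurrence-gated, linearly rank-discounted weight sum for one gene.

    ``ranks``/``weights`` are the gene's rank and elimination criterion in
    each list. Isolated here so the aggregation algebra can be replaced
    wholesale.
    """
    inside = ranks <= N
    if not np.any(inside):
        return 0.0
    return float(np.sum(weights[inside] * (N - ranks[inside] + 1) / N))


def aggregate_rankings(lists: list[RankedList], N: int, p: int | None = None) -> AggregateRanking:
    """Combine p ranked lists into one final ordering.

    Scored genes (top-N in at least one list) sort by score descending,
    ties by occurrence descending then probe id; never-occurring genes get
    score 0 and follow, ordered by mean rank ascending then probe id.
    """
    if not lists:
        raise DataError("no ranked lists to aggregate")
    if p is None:
        p = len(lists)
    if p != len(lists):
        raise ConfigError(f"p={p} does not match the {len(lists)} supplied lists")
    if N < 1:
        raise ConfigError(f"N must be >= 1, got {N}")
    if N > min(len(l) for l in lists):
        raise ConfigError(f"N={N} exceeds the shortest list length {min(len(l) for l in lists)}")

    universe: list[str] = []
    seen: set[str] = set()
    for fl in lists:
        for probe in fl.probe_ids:
            if probe not in seen:
                seen.add(probe)
                universe.append(probe)

    rank_maps = [fl.ranks() for fl in lists]
    crit_maps = [fl.criteria() for fl in lists]
    entries: list[AggregateEntry] = []
    for probe in universe:
        ranks, weights = [], []
        for rm, cm in zip(rank_maps, crit_maps):
            if probe in rm:
                ranks.append(rm[probe])
                weights.append(cm[probe])
        ranks_a = np.array(ranks, dtype=float)
        weights_a = np.array(weights, dtype=float)
        inside = ranks_a <= N
        entries.append(
            AggregateEntry(
                probe_id=probe,
                occurrence=int(inside.sum()),
                weight_sum=float(weights_a[inside].sum()),
                score=composite_score(ranks_a, weights_a, N),
                mean_rank=float(ranks_a.mean()),
                final_rank=0,
            )
        )

    scored = [e for e in entries if e.occurrence > 0]
    unscored = [e for e in entries if e.occurrence == 0]
    scored.sort(key=lambda e: (-e.score, -e.occurrence, e.probe_id))
    unscored.sort(key=lambda e: (e.mean_rank, e.probe_id))
    ordered = scored + unscored
    for rank, e in enumerate(ordered, start=1):
        e.final_rank = rank
    return AggregateRanking(n_lists=len(lists), top_n=N, entries=ordered)


def top_n_occurrence(lists: list[RankedList], probe_id: str, N: int) -> int:
    """Count the lists in which ``probe_id`` ranks within the top N.

    A gene absent from a list is treated as rank infinity there.
    """
    if not lists:
        raise DataError("no ranked lists supplied")
    count = 0
    for fl in lists:
        rank = fl.ranks().get(probe_id)
        if rank is not None and rank <= N:
            count += 1
    return count


def occurrence_table(lists: list[RankedList], probes: list[str], Ns: tuple[int, ...] = (10, 30)) -> dict[str, dict[int, int]]:
    """Stability report: per probe, top-N occurrence for each N."""
    rank_maps = [fl.ranks() for fl in lists]
    out: dict[str, dict[int, int]] = {}
    for probe in probes:
        out[probe] = {}
        for N in Ns:
            out[probe][N] = sum(1 for rm in rank_maps if rm.get(probe, np.inf) <= N)
    return out
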