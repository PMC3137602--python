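"""Per-gene two-sample t-test and p-value thresholding.

Reduces the gene universe before recursive elimination. Default is the
classical pooled-variance two-sample t with two-sided p-values; Welch's
unequal-variance variant is available by flag. No multiple-testing
correction is applied (the downstream selection expects a raw cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import ConfigError, DataError
from .io_core import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["GeneTestResult", "ttest_per_gene", "filter_by_pvalue"]


@dataclass
class GeneTestResult:
    probe_id: str
    t_statistic: float
    p_value: float
    df: float
    group_means: tuple[float, float]  # (class-1 mean, class-0 mean)
    degenerate: bool = False  # constant across all samples


def ttest_per_gene(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    variant: str = "pooled",
) -> list[GeneTestResult]:
    """Two-sided two-sample t-test for every probe.

    The t statistic is (class-1 mean - class-0 mean) / SE. Genes with zero
    variance in both groups and equal means get t=0, p=1 (flagged
    degenerate); zero pooled variance with unequal means gets p=0 with a
    logged warning.
    """
    if variant not in ("pooled", "welch"):
        raise ConfigError(f"unknown t-test variant {variant!r}")
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_samples:
        raise DataError(f"{matrix.n_samples} samples but {labels.shape[0]} labels")
    if not set(np.unique(labels).tolist()) <= {0, 1}:
        raise DataError(f"labels must be 0/1, got {np.unique(labels)}")
    g1 = matrix.values[:, labels == 1]
    g0 = matrix.values[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    if n1 < 2 or n0 < 2:
        raise DataError(f"each class needs >= 2 samples (got {n1} and {n0})")

    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v0 = g0.var(axis=1, ddof=1)
    diff = m1 - m0

    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "pooled":
            df = np.full(matrix.n_genes, float(n1 + n0 - 2))
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        else:
            a, b = v1 / n1, v0 / n0
            se = np.sqrt(a + b)
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n0 - 1))
            df = np.where(np.isfinite(df), df, float(n1 + n0 - 2))
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    zero_var = (v1 == 0) & (v0 == 0)
    equal_mean = diff == 0
    # equal means (incl. zero-variance case): t=0, p=1 by symmetry
    t = np.where(equal_mean, 0.0, t)
    p = np.where(equal_mean, 1.0, p)
    # zero spread but distinct means: infinitely significant
    sep = zero_var & ~equal_mean
    if np.any(sep):
        logger.warning(
            "%d gene(s) have zero within-group variance with unequal means; p set to 0",
            int(sep.sum()),
        )
        t = np.where(sep, np.sign(diff) * np.inf, t)
        p = np.where(sep, 0.0, p)

    return [
        GeneTestResult(
            probe_id=matrix.probe_ids[i],
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            df=float(df[i]),
            group_means=(float(m1[i]), float(m0[i])),
            degenerate=bool(zero_var[i] & equal_mean[i]),
        )
        for i in range(matrix.n_genes)
    ]


def filter_by_pvalue(results: list[GeneTestResult], alpha: float) -> list[str]:
    """Probe ids with p < alpha (strict), in input order."""
    if not results:
        raise DataError("no test results to filter")
    if not (0 < alpha <= 1):
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    return [r.probe_id for r in results if r.p_value < alpha]
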