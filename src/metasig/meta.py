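"""Per-gene effect sizes, random-effects pooling and significance filtering.

For each gene and cohort a standardized mean difference (Hedges' g,
case minus control) is computed with its sampling variance. Per-gene
effects are pooled across cohorts with the DerSimonian–Laird (DL)
moment estimator of the between-cohort variance tau^2, per-cohort
two-sided p-values are combined with Fisher's method (chi-square with
2k degrees of freedom), and the combined p-values are adjusted with
the Benjamini–Hochberg step-up over all genes. Candidate genes are
those passing both an absolute pooled-effect threshold and an FDR
threshold, split into up- and down-regulated lists by the sign of the
pooled effect.

Notation
--------
For one gene in one cohort with group sizes ``n1`` (case), ``n2``
(control) and pooled within-group SD ``s_p``::

    J = 1 - 3 / (4 (n1 + n2 - 2) - 1)            # small-sample correction
    g = J * (mean_case - mean_control) / s_p
    v = (n1 + n2) / (n1 n2) + g^2 / (2 (n1 + n2))

with a two-sided p-value from the normal approximation ``z = g / sqrt(v)``.
DL pooling over k cohorts uses fixed-effect weights ``w_i = 1/v_i``,
Cochran's ``Q = sum w_i (g_i - g_bar)^2``,
``tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` and
random-effects weights ``w*_i = 1/(v_i + tau^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CASE, CONTROL, CohortExpression

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # floor before logs so Fisher's statistic stays finite

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class GeneEffect:
    """Hedges' g for one gene in one cohort (case minus control)."""

    gene: str
    dataset_id: str
    g: float
    v: float
    n_case: int
    n_control: int
    p: float


@dataclass(frozen=True)
class PooledGene:
    """DL random-effects summary of one gene across cohorts."""

    gene: str
    k: int
    pooled_g: float
    se: float
    tau2: float
    Q: float
    z: float
    p_pooled: float
    fisher_stat: float
    fisher_p: float
    q: float
    direction: str


def hedges_g(case_values: Sequence[float], control_values: Sequence[float]) -> tuple[float, float, float]:
    """Hedges' g (case minus control), its variance, and a two-sided p-value.

    Requires at least two values per group and a positive pooled
    variance; swapping the groups negates g and leaves v unchanged.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 values (got {n1} and {n2})")
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance; gene should be excluded upstream")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = j * (case.mean() - control.mean()) / np.sqrt(sp2)
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    p = 2.0 * stats.norm.sf(abs(g) / np.sqrt(v))
    return float(g), float(v), float(p)


def cohort_effects(cohort: CohortExpression) -> list[GeneEffect]:
    """Per-gene Hedges' g for one labeled cohort, vectorized over genes.

    Genes with zero pooled within-group variance cannot be standardized
    and are excluded (counted in the log).
    """
    n1, n2 = cohort.class_counts()
    if n1 < 2 or n2 < 2:
        raise ValueError(f"{cohort.dataset_id}: needs >= 2 samples per class")
    case = cohort.class_values(CASE)
    control = cohort.class_values(CONTROL)
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * control.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    keep = sp2 > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("%s: excluded %d constant genes (zero pooled variance)",
                    cohort.dataset_id, n_excluded)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = j * (case.mean(axis=1) - control.mean(axis=1)) / np.sqrt(sp2)
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    p = 2.0 * stats.norm.sf(np.abs(g) / np.sqrt(v))
    genes = cohort.genes
    return [
        GeneEffect(str(genes[i]), cohort.dataset_id, float(g[i]), float(v[i]), n1, n2, float(p[i]))
        for i in np.flatnonzero(keep)
    ]


def dersimonian_laird(g: Sequence[float], v: Sequence[float]) -> tuple[float, float, float, float]:
    """DL random-effects pool of per-cohort effects.

    Returns ``(pooled_g, se, tau2, Q)``. A single study is returned
    unchanged with ``tau2 = Q = 0``; tau^2 is clipped at zero.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    if g.size == 0:
        raise ValueError("no effects to pool")
    if np.any(v <= 0):
        raise ValueError("all effect variances must be positive")
    if g.size == 1:
        return float(g[0]), float(np.sqrt(v[0])), 0.0, 0.0
    w = 1.0 / v
    g_fixed = float(w @ g / w.sum())
    q = float(w @ (g - g_fixed) ** 2)
    c = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (g.size - 1)) / c)
    w_star = 1.0 / (v + tau2)
    pooled = float(w_star @ g / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    return pooled, se, tau2, q


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test over independent p-values.

    ``X^2 = -2 sum ln p_i`` referred to chi-square with 2k degrees of
    freedom; p-values are floored at 1e-300 before the log.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(np.maximum(p, _P_FLOOR)).sum())
    return stat, float(stats.chi2.sf(stat, 2 * p.size))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def meta_analyze(cohorts: Sequence[CohortExpression]) -> list[PooledGene]:
    """Pool per-cohort Hedges' g across cohorts for every gene.

    Genes excluded in some cohorts (e.g. constant there) are pooled over
    the cohorts where they were estimable, so k can vary per gene. The
    q-value is the BH adjustment of the Fisher-combined p over all
    genes; direction is the sign of the pooled effect. The result is
    sorted by gene symbol and independent of cohort input order.
    """
    if not cohorts:
        raise ValueError("no cohorts given")
    effects = [cohort_effects(c) for c in sorted(cohorts, key=lambda c: c.dataset_id)]
    genes = sorted({e.gene for eff in effects for e in eff})
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_c, n_g = len(effects), len(genes)
    g_mat = np.full((n_c, n_g), np.nan)
    v_mat = np.full((n_c, n_g), np.nan)
    p_mat = np.full((n_c, n_g), np.nan)
    for row, eff in enumerate(effects):
        for e in eff:
            col = gene_idx[e.gene]
            g_mat[row, col], v_mat[row, col], p_mat[row, col] = e.g, e.v, e.p

    present = ~np.isnan(g_mat)
    k = present.sum(axis=0)
    if np.any(k == 0):
        raise ValueError("gene with no estimable effect in any cohort")
    g0 = np.where(present, g_mat, 0.0)
    w = np.where(present, 1.0 / np.where(present, v_mat, 1.0), 0.0)
    sw = w.sum(axis=0)
    g_fixed = (w * g0).sum(axis=0) / sw
    q_stat = (w * (g0 - g_fixed) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = sw - (w ** 2).sum(axis=0) / sw
        tau2 = np.where(k > 1, np.maximum(0.0, (q_stat - (k - 1)) / c), 0.0)
    w_star = np.where(present, 1.0 / np.where(present, v_mat + tau2[None, :], 1.0), 0.0)
    sws = w_star.sum(axis=0)
    pooled = (w_star * g0).sum(axis=0) / sws
    se = 1.0 / np.sqrt(sws)
    q_stat = np.where(k > 1, q_stat, 0.0)
    z = pooled / se
    p_pooled = 2.0 * stats.norm.sf(np.abs(z))
    logp = np.where(present, np.log(np.maximum(np.where(present, p_mat, 1.0), _P_FLOOR)), 0.0)
    fisher_stat = -2.0 * logp.sum(axis=0)
    fisher_p = stats.chi2.sf(fisher_stat, 2 * k)
    q_adj = bh_fdr(fisher_p)

    return [
        PooledGene(
            gene=genes[i], k=int(k[i]), pooled_g=float(pooled[i]), se=float(se[i]),
            tau2=float(tau2[i]), Q=float(q_stat[i]), z=float(z[i]),
            p_pooled=float(p_pooled[i]), fisher_stat=float(fisher_stat[i]),
            fisher_p=float(fisher_p[i]), q=float(q_adj[i]),
            direction=UP if pooled[i] > 0 else DOWN,
        )
        for i in range(n_g)
    ]


def select_significant(
    pooled: Iterable[PooledGene], es_min: float = 2.0, fdr_max: float = 0.01
) -> tuple[list[PooledGene], list[PooledGene]]:
    """Split genes passing |pooled_g| > es_min and q < fdr_max by direction.

    Both lists are sorted by |pooled_g| descending, then gene symbol, so
    downstream greedy search sees a deterministic candidate order.
    """
    if es_min <= 0:
        raise ValueError("es_min must be positive")
    if not 0 < fdr_max <= 1:
        raise ValueError("fdr_max must lie in (0, 1]")
    key = lambda pg: (-abs(pg.pooled_g), pg.gene)
    up = sorted((pg for pg in pooled if pg.pooled_g > es_min and pg.q < fdr_max), key=key)
    down = sorted((pg for pg in pooled if pg.pooled_g < -es_min and pg.q < fdr_max), key=key)
    return up, down


def pooled_table(pooled: Sequence[PooledGene]) -> pd.DataFrame:
    """Tabular view of meta-analysis results, one row per gene."""
    return pd.DataFrame(
        [
            (pg.gene, pg.k, pg.pooled_g, pg.se, pg.tau2, pg.Q, pg.z,
             pg.p_pooled, pg.fisher_stat, pg.fisher_p, pg.q, pg.direction)
            for pg in pooled
        ],
        columns=["gene", "k", "pooled_g", "se", "tau2", "Q", "z",
                 "p_pooled", "fisher_stat", "fisher_p", "q", "direction"],
    )


def write_pooled_table(pooled: Sequence[PooledGene], path: str | Path) -> None:
    pooled_table(pooled).to_csv(path, sep="\t", index=False)
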