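"""ROC curves, AUC confidence intervals and the cross-dataset summary AUC.

Per-dataset AUCs come with DeLong confidence intervals computed on the
logit scale (back-transformed and clipped to [0, 1]); the multi-cohort
summary AUC pools per-dataset logit-AUCs with the DerSimonian–Laird
random-effects estimator, using the Hanley–McNeil within-dataset
variance propagated to the logit scale by the delta method. Because
every quantity here is rank-based, any strictly increasing transform of
one dataset's scores leaves that dataset's ROC, AUC and interval
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .io import CASE, CohortExpression, Signature
from .meta import dersimonian_laird
from .search import cohort_scores, mann_whitney_auc

logger = logging.getLogger(__name__)

_AUC_CLAMP = 0.005  # keep logit finite at the boundaries
_VAR_FLOOR = 1e-8


@dataclass
class ScoreReport:
    """Scores and diagnostic performance of a signature over cohorts.

    per_sample : DataFrame with dataset_id, sample_id, class, meta_score.
    per_dataset : DataFrame with dataset_id, n_case, n_control, auc,
        ci_low, ci_high, missing_genes.
    summary : (summary_auc, ci_low, ci_high, k_datasets).
    """

    per_sample: pd.DataFrame
    per_dataset: pd.DataFrame
    summary: tuple[float, float, float, int]

    def write(self, outdir: str | Path, prefix: str = "") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(outdir / f"{prefix}per_sample.tsv", sep="\t", index=False)
        self.per_dataset.to_csv(outdir / f"{prefix}per_dataset.tsv", sep="\t", index=False)
        summary_auc_, lo, hi, k = self.summary
        pd.DataFrame(
            [(summary_auc_, lo, hi, k)],
            columns=["summary_auc", "ci_low", "ci_high", "k_datasets"],
        ).to_csv(outdir / f"{prefix}summary.tsv", sep="\t", index=False)


def _case_mask(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    return y == CASE


def roc_curve(scores: Sequence[float], labels) -> np.ndarray:
    """ROC points from a threshold sweep over the unique scores.

    Returns an (m, 2) array of (fpr, tpr) starting at (0, 0) and ending
    at (1, 1); its trapezoidal area equals the midrank AUC exactly,
    ties included.
    """
    s = np.asarray(scores, dtype=float)
    y = _case_mask(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC curve")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where a threshold block of tied scores ends
    last_in_block = np.flatnonzero(np.diff(s_sorted) != 0)
    block_ends = np.r_[last_in_block, s.size - 1]
    tp = np.cumsum(y_sorted)[block_ends]
    fp = block_ends + 1 - tp
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return np.column_stack([fpr, tpr])


def auc_ci(scores: Sequence[float], labels, level: float = 0.95) -> tuple[float, float, float]:
    """Midrank AUC with a DeLong confidence interval.

    The DeLong variance is computed from case/control placement values;
    the interval is normal on the logit scale, back-transformed and
    clipped to [0, 1]. A degenerate AUC of 0 or 1 gets a one-sided
    interval via a variance floor and clamped point estimate (with a
    warning).
    """
    s = np.asarray(scores, dtype=float)
    y = _case_mask(labels)
    case = s[y]
    control = s[~y]
    if case.size < 2 or control.size < 2:
        raise ValueError("need >= 2 samples per class for a confidence interval")
    cmp = (case[:, None] > control[None, :]).astype(float)
    cmp += 0.5 * (case[:, None] == control[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # placement value of each case among controls
    v01 = cmp.mean(axis=0)  # placement value of each control among cases
    var = float(v10.var(ddof=1) / case.size + v01.var(ddof=1) / control.size)
    if auc <= 0.0 or auc >= 1.0:
        logger.warning("degenerate AUC %.3f: one-sided interval via continuity fallback", auc)
    var = max(var, _VAR_FLOOR)
    a = float(np.clip(auc, _AUC_CLAMP, 1.0 - _AUC_CLAMP))
    var_logit = var / (a * (1.0 - a)) ** 2
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(expit(logit(a) - z * np.sqrt(var_logit)))
    hi = float(expit(logit(a) + z * np.sqrt(var_logit)))
    return auc, min(lo, auc), max(hi, auc)


def _hanley_mcneil_var(a: float, n_case: int, n_control: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    v = (a * (1.0 - a) + (n_case - 1) * (q1 - a * a) + (n_control - 1) * (q2 - a * a))
    return max(v / (n_case * n_control), _VAR_FLOOR)


def summary_auc(
    per_dataset: Sequence[tuple[float, int, int]], level: float = 0.95
) -> tuple[float, float, float]:
    """Random-effects pooled AUC over datasets, with a confidence interval.

    Each dataset's AUC (clamped to [0.005, 0.995]) is moved to the logit
    scale with its Hanley–McNeil variance propagated by the delta
    method, pooled with DerSimonian–Laird, and the pooled estimate and
    normal interval are back-transformed. A single dataset is returned
    as its own (clamped) AUC.
    """
    if not per_dataset:
        raise ValueError("no datasets to pool")
    logits, variances = [], []
    for a, n1, n0 in per_dataset:
        a = float(np.clip(a, _AUC_CLAMP, 1.0 - _AUC_CLAMP))
        logits.append(float(logit(a)))
        variances.append(_hanley_mcneil_var(a, n1, n0) / (a * (1.0 - a)) ** 2)
    mu, se, _tau2, _q = dersimonian_laird(logits, variances)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        float(expit(mu)),
        float(expit(mu - z * se)),
        float(expit(mu + z * se)),
    )


def validate_signature(
    cohorts: Sequence[CohortExpression], signature: Signature, level: float = 0.95
) -> ScoreReport:
    """Score a signature on labeled cohorts and summarize its performance.

    Cohorts missing some signature genes are scored on the genes
    present, with the missing genes listed in the per-dataset table; a
    cohort with no signature gene present raises.
    """
    sample_rows = []
    dataset_rows = []
    pooled_inputs = []
    for c in cohorts:
        present = set(c.genes)
        missing = sorted(g for g in signature.genes if g not in present)
        scores = cohort_scores(c, signature)
        for sample in c.samples:
            sample_rows.append((c.dataset_id, sample, c.labels.loc[sample], scores.loc[sample]))
        mask = (c.labels == CASE).to_numpy()
        auc, lo, hi = auc_ci(scores.to_numpy(), mask, level=level)
        n1, n0 = c.class_counts()
        dataset_rows.append((c.dataset_id, n1, n0, auc, lo, hi, ",".join(missing)))
        pooled_inputs.append((auc, n1, n0))
    s_auc, s_lo, s_hi = summary_auc(pooled_inputs, level=level)
    return ScoreReport(
        per_sample=pd.DataFrame(
            sample_rows, columns=["dataset_id", "sample_id", "class", "meta_score"]),
        per_dataset=pd.DataFrame(
            dataset_rows,
            columns=["dataset_id", "n_case", "n_control", "auc", "ci_low", "ci_high",
                     "missing_genes"]),
        summary=(s_auc, s_lo, s_hi, len(cohorts)),
    )


def roc_table(cohorts: Sequence[CohortExpression], signature: Signature) -> pd.DataFrame:
    """ROC points for every cohort as a long table (dataset_id, fpr, tpr)."""
    frames = []
    for c in cohorts:
        scores = cohort_scores(c, signature)
        pts = roc_curve(scores.to_numpy(), (c.labels == CASE).to_numpy())
        frames.append(pd.DataFrame({"dataset_id": c.dataset_id, "fpr": pts[:, 0], "tpr": pts[:, 1]}))
    return pd.concat(frames, ignore_index=True)
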