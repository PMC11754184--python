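"""Meta-score and greedy weighted-AUC signature search.

The meta-score of a sample is the mean log2 expression of the
signature's up-regulated genes minus the mean over the down-regulated
genes. A signature is scored on a cohort by the midrank (Mann–Whitney)
AUC of case vs. control meta-scores, and on a collection of cohorts by
the sample-size-weighted mean of per-cohort AUCs.

Forward search starts from the single candidate with the highest
weighted AUC and greedily adds the candidate giving the largest
increase, stopping when no addition improves the objective beyond a
configurable threshold. Backward search then removes genes whose
removal costs at most a configurable tolerance. Candidates are only
ever used in the direction assigned by the differential-expression
filter, and ties are broken deterministically (larger |pooled effect|,
then gene symbol), so the whole search is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CASE, CohortExpression, Signature
from .meta import DOWN, UP, PooledGene

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Greedy-search tuning knobs.

    forward_threshold : minimum weighted-AUC gain to accept an addition
        (0 means any strict improvement).
    backward_threshold : maximum weighted-AUC loss tolerated on removal
        (0 means only free removals).
    max_genes : optional cap on signature size.
    """

    forward_threshold: float = 0.0
    backward_threshold: float = 0.0
    max_genes: int | None = None

    def __post_init__(self) -> None:
        if self.forward_threshold < 0 or self.backward_threshold < 0:
            raise ValueError("search thresholds must be >= 0")
        if self.max_genes is not None and self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")


class Candidate(NamedTuple):
    gene: str
    direction: str
    effect: float


def _as_candidates(candidates) -> list[Candidate]:
    up_list, down_list = candidates
    out: list[Candidate] = []
    for direction, items in ((UP, up_list), (DOWN, down_list)):
        for item in items:
            if isinstance(item, PooledGene):
                out.append(Candidate(item.gene, direction, float(item.pooled_g)))
            elif isinstance(item, str):
                out.append(Candidate(item, direction, 0.0))
            else:
                gene, effect = item
                out.append(Candidate(str(gene), direction, float(effect)))
    return out


def sample_score(sample_values: Mapping[str, float], signature: Signature) -> float:
    """Meta-score of one sample: mean(up genes) - mean(down genes).

    A side with no genes (or with all of its genes missing from
    ``sample_values``) contributes 0; missing genes on a non-empty side
    are dropped from that side's mean. Raises if no signature gene is
    present at all.
    """
    up_vals = [sample_values[g] for g in signature.up if g in sample_values]
    down_vals = [sample_values[g] for g in signature.down if g in sample_values]
    if not up_vals and not down_vals:
        raise ValueError("no signature gene present in sample")
    up_mean = float(np.mean(up_vals)) if up_vals else 0.0
    down_mean = float(np.mean(down_vals)) if down_vals else 0.0
    return up_mean - down_mean


def cohort_scores(cohort: CohortExpression, signature: Signature) -> pd.Series:
    """Meta-score for every sample in a cohort.

    Signature genes absent from the cohort are dropped from their side
    with a single warning naming them; if no signature gene is present
    a ``ValueError`` naming the cohort is raised.
    """
    present = set(cohort.genes)
    missing = [g for g in signature.genes if g not in present]
    if missing:
        logger.warning("%s: signature genes missing from cohort: %s",
                       cohort.dataset_id, missing)
    up = [g for g in signature.up if g in present]
    down = [g for g in signature.down if g in present]
    if not up and not down:
        raise ValueError(f"{cohort.dataset_id}: no signature gene present in cohort")
    values = cohort.values
    up_mean = values.loc[up].mean(axis=0) if up else pd.Series(0.0, index=values.columns)
    down_mean = values.loc[down].mean(axis=0) if down else pd.Series(0.0, index=values.columns)
    scores = up_mean - down_mean
    scores.name = "meta_score"
    return scores


def mann_whitney_auc(case_scores: Sequence[float], control_scores: Sequence[float]) -> float:
    """Midrank AUC: probability a random case outscores a random control.

    Ties receive half credit, so this equals the normalized
    Mann–Whitney U statistic.
    """
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([case, control]))
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def dataset_auc(cohort: CohortExpression, signature: Signature) -> float:
    """Case-vs-control midrank AUC of the meta-score within one cohort."""
    scores = cohort_scores(cohort, signature)
    mask = (cohort.labels == CASE).to_numpy()
    if mask.all() or not mask.any():
        raise ValueError(f"{cohort.dataset_id}: both classes required for AUC")
    s = scores.to_numpy()
    return mann_whitney_auc(s[mask], s[~mask])


def weighted_auc(cohorts: Sequence[CohortExpression], signature: Signature) -> float:
    """Sample-size-weighted mean of per-cohort AUCs (the search objective)."""
    if not cohorts:
        raise ValueError("no cohorts given")
    num = 0.0
    den = 0
    for c in cohorts:
        num += c.n_samples * dataset_auc(c, signature)
        den += c.n_samples
    return num / den


# -- internal fast evaluation used by the greedy search ---------------------

class _Prepped(NamedTuple):
    rows: dict[str, np.ndarray]
    case_mask: np.ndarray
    n: int


def _prep(cohorts: Sequence[CohortExpression]) -> list[_Prepped]:
    out = []
    for c in cohorts:
        if c.labels is None:
            raise ValueError(f"{c.dataset_id}: cohort is unlabeled")
        mat = c.values.to_numpy(dtype=float)
        rows = {g: mat[i] for i, g in enumerate(c.genes)}
        out.append(_Prepped(rows, (c.labels == CASE).to_numpy(), c.n_samples))
    return out


def _eval_wauc(prepped: Sequence[_Prepped], up: Sequence[str], down: Sequence[str]) -> float:
    num = 0.0
    den = 0
    for rows, case_mask, n in prepped:
        up_rows = [rows[g] for g in up if g in rows]
        down_rows = [rows[g] for g in down if g in rows]
        s = np.zeros(n)
        if up_rows:
            s = s + np.mean(up_rows, axis=0)
        if down_rows:
            s = s - np.mean(down_rows, axis=0)
        num += n * mann_whitney_auc(s[case_mask], s[~case_mask])
        den += n
    return num / den


def _best_addition(evals: list[tuple[float, Candidate]]) -> tuple[float, Candidate]:
    # highest weighted AUC, then largest |effect|, then gene symbol
    return min(evals, key=lambda t: (-t[0], -abs(t[1].effect), t[1].gene))


def _best_removal(evals: list[tuple[float, Candidate]]) -> tuple[float, Candidate]:
    # highest weighted AUC after removal; ties remove the weakest effect
    # first so strongly differential genes are retained
    return min(evals, key=lambda t: (-t[0], abs(t[1].effect), t[1].gene))


def forward_search(
    cohorts: Sequence[CohortExpression],
    candidates,
    config: SearchConfig | None = None,
) -> Signature:
    """Greedy forward selection of signature genes on weighted AUC.

    ``candidates`` is a pair ``(up_candidates, down_candidates)`` whose
    items are :class:`~metasig.meta.PooledGene` objects, ``(gene,
    effect)`` pairs, or bare gene symbols. The first step picks the
    single best-discriminating candidate; each later step adds the
    candidate maximizing the new weighted AUC, accepted only if the
    improvement exceeds ``config.forward_threshold``.
    """
    config = config or SearchConfig()
    cands = _as_candidates(candidates)
    if not cands:
        raise ValueError("empty candidate set")
    prepped = _prep(cohorts)
    up: list[str] = []
    down: list[str] = []
    trace: list[dict] = []
    remaining = list(cands)
    selected: list[Candidate] = []
    current = -np.inf
    while remaining:
        if config.max_genes is not None and len(selected) >= config.max_genes:
            break
        evals = []
        for cand in remaining:
            trial_up = up + [cand.gene] if cand.direction == UP else up
            trial_down = down + [cand.gene] if cand.direction == DOWN else down
            evals.append((_eval_wauc(prepped, trial_up, trial_down), cand))
        wauc, best = _best_addition(evals)
        if selected and wauc - current <= config.forward_threshold:
            break
        (up if best.direction == UP else down).append(best.gene)
        selected.append(best)
        remaining.remove(best)
        current = wauc
        trace.append({"step": len(trace) + 1, "action": "add", "gene": best.gene,
                      "direction": best.direction, "weighted_auc": current})
    return Signature(
        up=up, down=down,
        metadata={"effects": {c.gene: c.effect for c in selected},
                  "weighted_auc": current},
        trace=trace,
    )


def backward_search(
    cohorts: Sequence[CohortExpression],
    signature: Signature,
    config: SearchConfig | None = None,
) -> Signature:
    """Greedy pruning: drop genes whose removal costs at most the tolerance.

    Repeatedly evaluates removal of every gene and removes the one
    leaving the highest weighted AUC, as long as the loss relative to
    the current objective is within ``config.backward_threshold``; at
    least one gene always remains. Tie-breaking matches forward search,
    using pooled effects recorded in ``signature.metadata['effects']``
    when available.
    """
    config = config or SearchConfig()
    if not signature.genes:
        raise ValueError("cannot prune an empty signature")
    prepped = _prep(cohorts)
    effects: Mapping[str, float] = signature.metadata.get("effects", {})
    up = list(signature.up)
    down = list(signature.down)
    trace = list(signature.trace)
    current = _eval_wauc(prepped, up, down)
    while len(up) + len(down) > 1:
        evals = []
        for direction, genes in ((UP, up), (DOWN, down)):
            for g in genes:
                trial_up = [x for x in up if x != g] if direction == UP else up
                trial_down = [x for x in down if x != g] if direction == DOWN else down
                cand = Candidate(g, direction, float(effects.get(g, 0.0)))
                evals.append((_eval_wauc(prepped, trial_up, trial_down), cand))
        wauc, best = _best_removal(evals)
        if current - wauc > config.backward_threshold:
            break
        (up if best.direction == UP else down).remove(best.gene)
        current = wauc
        trace.append({"step": len(trace) + 1, "action": "remove", "gene": best.gene,
                      "direction": best.direction, "weighted_auc": current})
    meta = dict(signature.metadata)
    meta["weighted_auc"] = current
    meta["effects"] = {g: float(effects.get(g, 0.0)) for g in up + down}
    return Signature(up=up, down=down, metadata=meta, trace=trace)


def discover_signature(
    cohorts: Sequence[CohortExpression],
    candidates,
    config: SearchConfig | None = None,
) -> Signature:
    """Forward search followed by one backward pruning pass."""
    return backward_search(cohorts, forward_search(cohorts, candidates, config), config)


def write_trace(signature: Signature, path: str | Path) -> None:
    """Export the search trace as TSV (step, action, gene, direction, weighted_auc)."""
    df = pd.DataFrame(signature.trace,
                      columns=["step", "action", "gene", "direction", "weighted_auc"])
    df.to_csv(path, sep="\t", index=False)
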