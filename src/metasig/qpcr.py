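"""Relative quantification from triplicate Ct values (2^-ddCt) and scoring.

Technical replicates are collapsed to a per-(sample, gene) mean Ct with
a simple QC rule (replicate SD above a cycle threshold flags the entry
out). Relative expression follows the classic comparative-Ct scheme
with a single reference gene and amplification efficiency fixed at 2::

    dCt  = Ct_target - Ct_reference            (per sample)
    ddCt = dCt - mean(dCt over control group)  (per gene)
    relative expression = 2^(-ddCt), log2 relative expression = -ddCt

Signature scoring applies the tissue meta-score (mean up minus mean
down) to the log2 relative expression, keeping blood qPCR data on the
same log2 scale as the expression matrices.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .evaluate import auc_ci
from .io import CASE, Signature
from .search import sample_score

logger = logging.getLogger(__name__)

REFERENCE_GENE = "GAPDH"

_CT_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct"]
_UNDETERMINED = {"", "NA", "NaN", "nan", "Undetermined", "undetermined"}


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV (sample_id, group, gene, replicate, ct).

    Undetermined/missing Ct tokens become NaN (absent replicates);
    numeric Ct values must lie in (0, 40].
    """
    table = pd.read_csv(path, dtype={"sample_id": str, "gene": str})
    missing = set(_CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    ct = table["ct"]
    if ct.dtype == object:
        ct = ct.where(~ct.astype(str).str.strip().isin(_UNDETERMINED))
        table["ct"] = pd.to_numeric(ct)
    bad = table["ct"].notna() & ((table["ct"] <= 0) | (table["ct"] > 40))
    if bad.any():
        raise ValueError(f"{path}: Ct values outside (0, 40]")
    return table


def collapse_triplicates(table: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, gene) with a replicate-consistency QC flag.

    Entries whose replicate SD exceeds ``max_sd`` cycles are flagged
    (``qc_pass = False``) and excluded downstream. Missing Ct values
    count as absent replicates; a single replicate passes (SD treated
    as 0). A (sample, gene) with zero usable replicates raises.
    """
    if table.empty:
        raise ValueError("empty Ct table")
    grouped = table.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
    out = grouped.agg(ct_mean="mean", ct_sd="std", n_replicates="count").reset_index()
    if (out["n_replicates"] == 0).any():
        bad = out.loc[out["n_replicates"] == 0, ["sample_id", "gene"]].to_records(index=False)
        raise ValueError(f"no usable replicates for {list(bad)}")
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    out["qc_pass"] = out["ct_sd"] <= max_sd
    n_flagged = int((~out["qc_pass"]).sum())
    if n_flagged:
        logger.warning("flagged %d (sample, gene) entries with replicate SD > %.2f cycles",
                       n_flagged, max_sd)
    return out


def delta_delta_ct(
    mean_ct: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-(sample, gene) relative expression by the comparative-Ct method.

    ``mean_ct`` is the output of :func:`collapse_triplicates` (rows
    failing QC are ignored). Requires a reference-gene Ct for every
    retained sample and at least one control-group sample per gene.
    """
    df = mean_ct[mean_ct["qc_pass"]] if "qc_pass" in mean_ct.columns else mean_ct
    measured_ref = set(mean_ct.loc[mean_ct["gene"] == reference_gene, "sample_id"])
    ref = df[df["gene"] == reference_gene].set_index("sample_id")["ct_mean"]
    targets = df[df["gene"] != reference_gene].copy()
    if targets.empty:
        raise ValueError("no target genes in Ct table")
    no_ref = sorted(set(targets["sample_id"]) - measured_ref)
    if no_ref:
        raise ValueError(f"missing reference-gene Ct for samples {no_ref}")
    # reference measured but flagged out by QC: the sample cannot be
    # normalized, so it is dropped rather than quantified against nothing
    qc_dropped = sorted(set(targets["sample_id"]) - set(ref.index))
    if qc_dropped:
        logger.warning("dropping samples whose reference gene failed replicate QC: %s",
                       qc_dropped)
        targets = targets[~targets["sample_id"].isin(qc_dropped)]
    targets["delta_ct"] = targets["ct_mean"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()
    out = []
    for gene, sub in targets.groupby("gene", sort=True):
        ctrl = sub.loc[sub["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control-group samples")
        ddct = sub["delta_ct"] - ctrl.mean()
        sub = sub.assign(delta_delta_ct=ddct, rel_expr=2.0 ** (-ddct), log2_rel_expr=-ddct)
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result[["sample_id", "group", "gene", "delta_ct", "delta_delta_ct",
                   "rel_expr", "log2_rel_expr"]]


def qpcr_signature_score(
    relative_expression: pd.DataFrame,
    signature: Signature,
    level: float = 0.95,
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Meta-score each sample on log2 relative expression, with AUC + CI.

    Returns ``(scores, (auc, ci_low, ci_high))`` where ``scores`` has
    columns sample_id, group, meta_score.
    """
    rows = []
    for (sample_id, group), sub in relative_expression.groupby(["sample_id", "group"], sort=True):
        values = dict(zip(sub["gene"], sub["log2_rel_expr"]))
        rows.append((sample_id, group, sample_score(values, signature)))
    scores = pd.DataFrame(rows, columns=["sample_id", "group", "meta_score"])
    labels = (scores["group"] == CASE).to_numpy()
    ci = auc_ci(scores["meta_score"].to_numpy(), labels, level=level)
    return scores, ci


def write_relative_expression(rel: pd.DataFrame, path: str | Path) -> None:
    rel.to_csv(path, sep="\t", index=False)
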