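"""Reading and writing cohorts, phenotype tables and signature files.

File formats
------------
Expression matrix
    UTF-8 TSV, header ``gene_symbol<TAB>sample1<TAB>...``, one row per
    gene, already-normalized log2-scale values. Empty cells, ``NA`` and
    ``NaN`` are the only accepted missing tokens; any gene row containing
    a missing or non-finite value is dropped (and counted in the log),
    because downstream meta-scores require a complete value for every
    signature gene in every sample. Duplicate gene symbols (e.g. multiple
    probes mapping to one gene) are collapsed by keeping the row with the
    highest mean expression.
Phenotype
    TSV with columns ``sample_id``, ``dataset_id``, ``class``. Class
    labels are matched case-insensitively against an alias map
    (tumor/cancer/PDAC -> case, normal/healthy/control -> control).
Signature
    JSON object ``{"up": [...], "down": [...], "metadata": {...}}``.

Gene symbols are uppercased on ingestion so that cohorts from different
platforms share a symbol universe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: Accepted class spellings, lowercased. Matches the heterogeneous labels
#: typically found in public tumor/normal series.
DEFAULT_CLASS_ALIASES: Mapping[str, str] = {
    "case": CASE,
    "tumor": CASE,
    "tumour": CASE,
    "cancer": CASE,
    "pdac": CASE,
    "control": CONTROL,
    "normal": CONTROL,
    "healthy": CONTROL,
}

_MISSING_TOKENS = ["", "NA", "NaN", "nan"]


@dataclass
class CohortExpression:
    """One dataset's log2 expression matrix plus optional case/control labels.

    Parameters
    ----------
    dataset_id : str
        Identifier of the cohort (e.g. a GEO accession).
    values : pandas.DataFrame
        Genes x samples matrix of log2 expression. The index holds unique
        uppercase gene symbols, the columns unique sample IDs.
    labels : pandas.Series, optional
        Per-sample class, ``"case"`` or ``"control"``, indexed by sample
        ID. ``None`` for an unlabeled matrix fresh from disk.
    """

    dataset_id: str
    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.dataset_id}: duplicate gene symbols {dups}")
        if self.values.columns.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicate sample IDs")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.dataset_id}: non-finite expression values")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise ValueError(f"{self.dataset_id}: unlabeled samples {missing}")
            bad = set(self.labels.unique()) - {CASE, CONTROL}
            if bad:
                raise ValueError(f"{self.dataset_id}: unknown classes {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """Return ``(n_case, n_control)``; requires labels."""
        if self.labels is None:
            raise ValueError(f"{self.dataset_id}: cohort is unlabeled")
        return int((self.labels == CASE).sum()), int((self.labels == CONTROL).sum())

    def class_values(self, cls: str) -> np.ndarray:
        """Genes x samples array restricted to one class."""
        if self.labels is None:
            raise ValueError(f"{self.dataset_id}: cohort is unlabeled")
        mask = (self.labels == cls).to_numpy()
        return self.values.to_numpy(dtype=float)[:, mask]

    def subset_genes(self, genes: Sequence[str]) -> "CohortExpression":
        return CohortExpression(self.dataset_id, self.values.loc[list(genes)], self.labels)


@dataclass
class Signature:
    """Up/down gene lists with free-form metadata and an optional search trace.

    The serialized form (see :func:`write_signature`) carries ``up``,
    ``down`` and ``metadata`` only; the search trace is exported
    separately as a TSV (:func:`metasig.search.write_trace`).
    """

    up: list[str]
    down: list[str]
    metadata: dict = field(default_factory=dict)
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"genes in both up and down lists: {sorted(overlap)}")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)


def read_expression_matrix(path: str | Path, dataset_id: str | None = None) -> CohortExpression:
    """Read a TSV expression matrix into an unlabeled :class:`CohortExpression`.

    Gene symbols are uppercased; duplicate symbols are collapsed to the
    row with the highest mean expression; rows with any missing value are
    dropped. Raises ``ValueError`` for non-numeric cells that are not an
    accepted missing token, and for matrices with fewer than 2 samples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=_MISSING_TOKENS, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression matrix needs at least 2 samples")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene_symbol"

    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("%s: dropped %d gene rows with missing/non-finite values", path.name, n_dropped)
        df = df.loc[finite]

    if df.index.duplicated().any():
        n_before = df.shape[0]
        means = df.mean(axis=1)
        order = np.lexsort((-means.to_numpy(), df.index.to_numpy()))
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        logger.info("%s: collapsed %d duplicate gene rows (kept highest mean)",
                    path.name, n_before - df.shape[0])
    if df.empty:
        raise ValueError(f"{path}: no usable gene rows after filtering")
    return CohortExpression(dataset_id or path.stem, df)


def write_expression_matrix(cohort: CohortExpression, path: str | Path) -> None:
    df = cohort.values.copy()
    df.index.name = "gene_symbol"
    df.to_csv(path, sep="\t")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns sample_id, dataset_id, class."""
    ph = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "dataset_id", "class"}
    missing = required - set(ph.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    if ph.duplicated(["sample_id", "dataset_id"]).any():
        raise ValueError(f"{path}: duplicate (sample_id, dataset_id) pairs")
    return ph


def write_phenotype(ph: pd.DataFrame, path: str | Path) -> None:
    ph.to_csv(path, sep="\t", index=False)


def assemble_cohorts(
    matrices: Iterable[CohortExpression],
    phenotype: pd.DataFrame,
    class_aliases: Mapping[str, str] | None = None,
) -> list[CohortExpression]:
    """Attach case/control labels from a phenotype table.

    Samples absent from the phenotype table are dropped with a warning.
    Every labeled cohort must retain at least 2 case and 2 control
    samples; otherwise a ``ValueError`` naming the cohort is raised.
    """
    aliases = dict(DEFAULT_CLASS_ALIASES if class_aliases is None else class_aliases)
    if phenotype.duplicated(["sample_id", "dataset_id"]).any():
        raise ValueError("phenotype table has duplicate (sample_id, dataset_id) pairs")
    out = []
    for m in matrices:
        ph = phenotype[phenotype["dataset_id"] == m.dataset_id]
        if ph.empty:
            raise KeyError(f"dataset {m.dataset_id!r} missing from phenotype table")
        raw = ph.set_index("sample_id")["class"].astype(str)
        unknown = sorted(set(raw.str.lower()) - set(aliases))
        if unknown:
            raise ValueError(f"{m.dataset_id}: unknown class labels {unknown}")
        labels = raw.str.lower().map(aliases)
        keep = [s for s in m.samples if s in labels.index]
        dropped = [s for s in m.samples if s not in labels.index]
        if dropped:
            logger.warning("%s: dropping %d samples absent from phenotype: %s",
                           m.dataset_id, len(dropped), dropped)
        labels = labels.loc[keep]
        n_case = int((labels == CASE).sum())
        n_control = int((labels == CONTROL).sum())
        if n_case < 2 or n_control < 2:
            raise ValueError(
                f"cohort {m.dataset_id!r} has {n_case} case / {n_control} control "
                "samples; at least 2 of each are required")
        out.append(CohortExpression(m.dataset_id, m.values[keep], labels))
    return out


def intersect_genes(cohorts: Sequence[CohortExpression]) -> list[CohortExpression]:
    """Restrict all cohorts to the sorted intersection of their gene sets."""
    if not cohorts:
        raise ValueError("no cohorts given")
    shared: set[str] = set(cohorts[0].genes)
    for c in cohorts[1:]:
        shared &= set(c.genes)
    if not shared:
        raise ValueError("gene-set intersection across cohorts is empty")
    ordered = sorted(shared)
    return [c.subset_genes(ordered) for c in cohorts]


def _check_signature(sig: Signature) -> None:
    if not sig.up and not sig.down:
        raise ValueError("signature has neither up nor down genes")
    overlap = set(sig.up) & set(sig.down)
    if overlap:
        raise ValueError(f"genes in both up and down lists: {sorted(overlap)}")


def read_signature(path: str | Path) -> Signature:
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict) or "up" not in obj or "down" not in obj:
        raise ValueError(f"{path}: malformed signature file")
    sig = Signature(list(obj["up"]), list(obj["down"]), dict(obj.get("metadata", {})))
    _check_signature(sig)
    return sig


def write_signature(sig: Signature, path: str | Path) -> None:
    _check_signature(sig)
    obj = {"up": list(sig.up), "down": list(sig.down), "metadata": sig.metadata}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
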