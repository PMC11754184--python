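"""End-to-end reproducible runs: simulate, discover, validate, qpcr.

Each run writes its artifacts plus a ``manifest.json`` recording the
configuration, package version, seed and SHA-256 checksums of the
inputs, so every reported AUC can be traced to its exact inputs.
Identical configuration and inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .evaluate import roc_table, validate_signature
from .io import (CohortExpression, Signature, assemble_cohorts, intersect_genes,
                 read_expression_matrix, read_phenotype, read_signature,
                 write_expression_matrix, write_phenotype, write_signature)
from .meta import meta_analyze, pooled_table, select_significant, write_pooled_table
from .qpcr import (REFERENCE_GENE, collapse_triplicates, delta_delta_ct,
                   qpcr_signature_score, read_ct_table, write_relative_expression)
from .search import SearchConfig, discover_signature, write_trace
from .simulate import SimConfig, generate_multicohort, generate_qpcr, planted_signature

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a discovery/validation run.

    ``expression`` maps dataset IDs to expression-matrix TSV paths;
    ``training`` and ``validation`` are disjoint dataset-ID lists.
    """

    expression: dict[str, str]
    phenotype: str
    training: list[str]
    validation: list[str] = field(default_factory=list)
    es_min: float = 2.0
    fdr_max: float = 0.01
    forward_threshold: float = 0.0
    backward_threshold: float = 0.0
    max_genes: int | None = None
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not self.training:
            raise ValueError("training dataset list is empty")
        overlap = set(self.training) & set(self.validation)
        if overlap:
            raise ValueError(f"datasets in both training and validation: {sorted(overlap)}")
        for ds in [*self.training, *self.validation]:
            if ds not in self.expression:
                raise ValueError(f"dataset {ds!r} has no expression path")
        if self.es_min <= 0:
            raise ValueError("es_min must be positive")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.forward_threshold < 0 or self.backward_threshold < 0:
            raise ValueError("search thresholds must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        obj.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**obj)

    def search_config(self) -> SearchConfig:
        return SearchConfig(self.forward_threshold, self.backward_threshold, self.max_genes)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: dict, inputs: dict[str, str]) -> None:
    manifest = {
        "stage": stage,
        "metasig_version": __version__,
        "config": config,
        "input_sha256": {name: _sha256(p) for name, p in inputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_cohorts(config: RunConfig, dataset_ids: list[str]) -> list[CohortExpression]:
    phenotype = read_phenotype(config.phenotype)
    matrices = [read_expression_matrix(config.expression[ds], dataset_id=ds)
                for ds in dataset_ids]
    return intersect_genes(assemble_cohorts(matrices, phenotype))


def run_discover(config: RunConfig) -> dict:
    """Full discovery: meta-analysis, candidate filtering, greedy search.

    Writes pooled_genes.tsv, candidates_up/down.tsv, signature.json,
    search_trace.tsv, the training ScoreReport TSVs, training ROC
    points and a manifest. Returns a dict of artifact paths plus the
    discovered signature.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = _load_cohorts(config, config.training)
    pooled = meta_analyze(cohorts)
    write_pooled_table(pooled, outdir / "pooled_genes.tsv")
    up, down = select_significant(pooled, config.es_min, config.fdr_max)
    for name, cands in (("candidates_up", up), ("candidates_down", down)):
        pooled_table(cands).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if not up and not down:
        raise ValueError(
            "discover: no candidate genes pass the effect-size/FDR filter")
    signature = discover_signature(cohorts, (up, down), config.search_config())
    write_signature(signature, outdir / "signature.json")
    write_trace(signature, outdir / "search_trace.tsv")
    report = validate_signature(cohorts, signature)
    report.write(outdir, prefix="training_")
    roc_table(cohorts, signature).to_csv(outdir / "training_roc.tsv", sep="\t", index=False)
    inputs = {ds: config.expression[ds] for ds in config.training}
    inputs["phenotype"] = config.phenotype
    _write_manifest(outdir, "discover", dataclasses.asdict(config), inputs)
    return {"signature": signature, "report": report, "outdir": outdir}


def run_validate(config: RunConfig, signature_path: str | Path) -> dict:
    """Score a saved signature on the validation cohorts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.validation:
        raise ValueError("validate: validation dataset list is empty")
    signature = read_signature(signature_path)
    cohorts = _load_cohorts(config, config.validation)
    report = validate_signature(cohorts, signature)
    report.write(outdir, prefix="validation_")
    roc_table(cohorts, signature).to_csv(outdir / "validation_roc.tsv", sep="\t", index=False)
    inputs = {ds: config.expression[ds] for ds in config.validation}
    inputs["phenotype"] = config.phenotype
    inputs["signature"] = str(signature_path)
    _write_manifest(outdir, "validate", dataclasses.asdict(config), inputs)
    return {"signature": signature, "report": report, "outdir": outdir}


def run_simulate(
    sim_config: SimConfig,
    outdir: str | Path,
    *,
    qpcr_n_case: int = 30,
    qpcr_n_control: int = 25,
    qpcr_log2_fold_change: float = 2.5,
) -> dict:
    """Write synthetic fixture files: expression TSVs, phenotype, qPCR CSV.

    The qPCR table covers the planted signature genes at the given log2
    fold change (sign following each gene's planted direction), sized
    by default like a modest blood validation cohort.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = generate_multicohort(sim_config)
    phenotype_rows = []
    expression_paths: dict[str, str] = {}
    for c in cohorts:
        path = outdir / f"{c.dataset_id}.tsv"
        write_expression_matrix(c, path)
        expression_paths[c.dataset_id] = str(path)
        for sample in c.samples:
            phenotype_rows.append((sample, c.dataset_id, c.labels.loc[sample]))
    import pandas as pd

    phenotype = pd.DataFrame(phenotype_rows, columns=["sample_id", "dataset_id", "class"])
    write_phenotype(phenotype, outdir / "phenotype.tsv")
    truth = planted_signature(sim_config)
    qpcr_path = None
    if truth.genes:
        fold_changes = {g: qpcr_log2_fold_change for g in truth.up}
        fold_changes.update({g: -qpcr_log2_fold_change for g in truth.down})
        table = generate_qpcr(qpcr_n_case, qpcr_n_control, truth, fold_changes,
                              seed=sim_config.seed)
        qpcr_path = outdir / "qpcr_ct.csv"
        table.to_csv(qpcr_path, index=False)
        write_signature(truth, outdir / "planted_signature.json")
    _write_manifest(outdir, "simulate", dataclasses.asdict(sim_config), {})
    return {"expression": expression_paths, "phenotype": str(outdir / "phenotype.tsv"),
            "qpcr": str(qpcr_path) if qpcr_path else None, "outdir": outdir}


def run_qpcr(
    ct_path: str | Path,
    signature_path: str | Path,
    outdir: str | Path,
    *,
    reference_gene: str = REFERENCE_GENE,
    control_group: str = "control",
) -> dict:
    """Relative quantification and signature scoring of a Ct table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signature = read_signature(signature_path)
    table = read_ct_table(ct_path)
    mean_ct = collapse_triplicates(table)
    rel = delta_delta_ct(mean_ct, reference_gene=reference_gene,
                         control_group=control_group)
    write_relative_expression(rel, outdir / "relative_expression.tsv")
    scores, (auc, lo, hi) = qpcr_signature_score(rel, signature)
    scores.to_csv(outdir / "qpcr_scores.tsv", sep="\t", index=False)
    with open(outdir / "qpcr_auc.json", "w") as fh:
        json.dump({"auc": auc, "ci_low": lo, "ci_high": hi,
                   "n_samples": int(scores.shape[0])}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(outdir, "qpcr", {"reference_gene": reference_gene,
                                     "control_group": control_group},
                    {"ct_table": str(ct_path), "signature": str(signature_path)})
    return {"scores": scores, "auc": (auc, lo, hi), "outdir": outdir}
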