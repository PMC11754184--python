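"""Synthetic multi-cohort expression data and qPCR tables with known truth.

The generator emulates the structure of a multi-cohort case/control
microarray compendium: per-gene log2 baselines drawn uniformly over a
typical intensity range, Gaussian within-group noise, and a small set
of planted differentially expressed genes whose per-cohort effect is
drawn around a common standardized effect size ``delta`` with
between-cohort SD ``tau``. Effects are planted on the standardized
scale (mean shift = delta * sigma), so the true Hedges' g of a planted
gene is ``delta`` by construction and parameter recovery can be checked
exactly in expectation.

Each cohort uses an independent random substream derived from
``(seed, dataset_index)``; increasing ``n_datasets`` therefore extends
the collection without altering earlier cohorts.

A companion generator produces triplicate-Ct qPCR tables with a
reference gene, for exercising the relative-quantification path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, CohortExpression, Signature


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for a synthetic multi-cohort study.

    Defaults describe a desk-scale study: six cohorts of 20 cases and
    20 controls, 1000 genes, five planted up-regulated genes with true
    standardized effect 2.5 and between-cohort SD 0.1, unit within-group
    SD, and log2 baselines spanning the usual microarray range [4, 12].
    """

    n_datasets: int = 6
    n_case: int = 20
    n_control: int = 20
    n_genes: int = 1000
    planted_up: tuple[int, ...] = (0, 1, 2, 3, 4)
    planted_down: tuple[int, ...] = ()
    delta: float = 2.5
    tau: float = 0.1
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 case and >= 2 control samples per cohort")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted up and down gene sets overlap")
        for idx in (*self.planted_up, *self.planted_down):
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted gene index {idx} out of range")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ValueError("baseline_mean_range must be an increasing interval")

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def generate_multicohort(config: SimConfig) -> list[CohortExpression]:
    """Draw labeled case/control cohorts from a :class:`SimConfig`.

    Substream ``(seed, 0)`` fixes the shared per-gene baselines;
    substream ``(seed, k+1)`` drives cohort k, so results are fully
    reproducible and extensible in ``n_datasets``.
    """
    genes = config.gene_names()
    lo, hi = config.baseline_mean_range
    mu = np.random.default_rng([config.seed, 0]).uniform(lo, hi, config.n_genes)
    cohorts = []
    for k in range(config.n_datasets):
        rng = np.random.default_rng([config.seed, k + 1])
        delta_gk = np.zeros(config.n_genes)
        if config.planted_up:
            delta_gk[list(config.planted_up)] = rng.normal(
                config.delta, config.tau, len(config.planted_up))
        if config.planted_down:
            delta_gk[list(config.planted_down)] = rng.normal(
                -config.delta, config.tau, len(config.planted_down))
        case = rng.normal((mu + delta_gk * config.sigma)[:, None], config.sigma,
                          (config.n_genes, config.n_case))
        control = rng.normal(mu[:, None], config.sigma,
                             (config.n_genes, config.n_control))
        dataset_id = f"SIM{k + 1:02d}"
        case_ids = [f"{dataset_id}_case{i + 1:03d}" for i in range(config.n_case)]
        control_ids = [f"{dataset_id}_ctrl{i + 1:03d}" for i in range(config.n_control)]
        values = pd.DataFrame(np.hstack([case, control]), index=genes,
                              columns=case_ids + control_ids)
        values.index.name = "gene_symbol"
        labels = pd.Series([CASE] * config.n_case + [CONTROL] * config.n_control,
                           index=values.columns)
        cohorts.append(CohortExpression(dataset_id, values, labels))
    return cohorts


def generate_null(config: SimConfig) -> list[CohortExpression]:
    """Global-null variant of :func:`generate_multicohort` (no planted genes)."""
    return generate_multicohort(replace(config, planted_up=(), planted_down=()))


def planted_signature(config: SimConfig) -> Signature:
    """The true signature implied by a config's planted gene sets."""
    genes = config.gene_names()
    return Signature(
        up=[genes[i] for i in config.planted_up],
        down=[genes[i] for i in config.planted_down],
        metadata={"source": "planted truth"},
    )


def generate_qpcr(
    n_case: int,
    n_control: int,
    signature: Signature,
    fold_changes: Mapping[str, float],
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    *,
    reference_gene: str = "GAPDH",
    biological_sd: float = 0.5,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate-Ct qPCR table for a signature with known log2 fold changes.

    ``fold_changes`` maps signature genes to their true case/control
    log2 fold change (genes not listed get 0). Per sample, the
    reference-gene Ct is drawn N(20, 0.2^2); per gene, the control-group
    delta-Ct is drawn around a fixed per-gene baseline with SD
    ``biological_sd``, cases are shifted by minus the log2 fold change
    (more transcript = fewer cycles), and each (sample, gene) gets
    ``n_replicates`` technical replicates with SD ``ct_noise_sd``.

    Returns a DataFrame with columns sample_id, group, gene, replicate, ct.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("n_case and n_control must be >= 1")
    if ct_noise_sd < 0 or biological_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    unknown = set(fold_changes) - set(signature.genes)
    if unknown:
        raise ValueError(f"fold_changes for genes not in the signature: {sorted(unknown)}")
    rng = np.random.default_rng([seed])
    genes = signature.genes
    baselines = {g: rng.uniform(2.0, 10.0) for g in genes}
    rows = []
    samples = [(f"case{i + 1:03d}", CASE) for i in range(n_case)] + \
              [(f"ctrl{i + 1:03d}", CONTROL) for i in range(n_control)]
    for sample_id, group in samples:
        ref_true = rng.normal(20.0, 0.2)
        for rep in range(1, n_replicates + 1):
            rows.append((sample_id, group, reference_gene, rep,
                         rng.normal(ref_true, ct_noise_sd)))
        for g in genes:
            dct = rng.normal(baselines[g], biological_sd)
            if group == CASE:
                dct -= float(fold_changes.get(g, 0.0))
            target_true = ref_true + dct
            for rep in range(1, n_replicates + 1):
                rows.append((sample_id, group, g, rep, rng.normal(target_true, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"])
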