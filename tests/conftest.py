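import numpy as np
import pandas as pd
import pytest

from metasig import CohortExpression, Signature, SimConfig, generate_multicohort
from metasig.io import CASE, CONTROL


def make_cohort(dataset_id, genes, case, control, rng=None):
    """Build a labeled cohort from per-class genes x samples arrays."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    samples = [f"{dataset_id}_c{i}" for i in range(n1)] + \
              [f"{dataset_id}_n{i}" for i in range(n2)]
    values = pd.DataFrame(np.hstack([case, control]), index=list(genes), columns=samples)
    labels = pd.Series([CASE] * n1 + [CONTROL] * n2, index=samples)
    return CohortExpression(dataset_id, values, labels)


@pytest.fixture
def two_gene_signature():
    return Signature(up=["UPA", "UPB"], down=["DNA"])


@pytest.fixture
def small_cohorts():
    """Two small labeled cohorts with one strongly separating gene."""
    rng = np.random.default_rng(42)
    cohorts = []
    for k, ds in enumerate(["D1", "D2"]):
        genes = ["SEP", "NOISE1", "NOISE2"]
        case = rng.normal(0, 1, (3, 8))
        control = rng.normal(0, 1, (3, 8))
        case[0] += 4.0  # SEP separates the classes
        cohorts.append(make_cohort(ds, genes, case, control))
    return cohorts


@pytest.fixture
def planted_cohorts():
    """Six simulated cohorts with five planted up-regulated genes."""
    return generate_multicohort(SimConfig(n_genes=200, seed=7))


def write_cohort_tsv(cohort, path):
    df = cohort.values.copy()
    df.index.name = "gene_symbol"
    df.to_csv(path, sep="\t")
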