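import numpy as np
import pandas as pd
import pytest

from gsrlab.core import gsr_matrix
from gsrlab.io import ExpressionMatrix, GeneSet, GeneSetCollection, PhenotypeTable
from gsrlab.simulate import SyntheticConfig, generate_cohort, staging_preset


@pytest.fixture(scope="session")
def staging_cohort():
    """One staging-preset cohort, shared across tests (seed fixed)."""
    return generate_cohort(staging_preset(seed=1))


@pytest.fixture(scope="session")
def staging_gsr(staging_cohort):
    expr, phenotypes, collection, _ = staging_cohort
    return gsr_matrix(expr, phenotypes, collection)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Low-noise default configuration used for parameter-recovery checks."""
    return generate_cohort(SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def recovery_gsr(recovery_cohort):
    expr, phenotypes, collection, _ = recovery_cohort
    return gsr_matrix(expr, phenotypes, collection)


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples with a fixed strict ordering g1<g2<g3<g4 in controls."""
    rng = np.random.default_rng(7)
    base = np.array([1.0, 2.0, 3.0, 4.0])
    cols = {}
    for i in range(4):
        cols[f"ctl{i}"] = base + rng.uniform(-0.2, 0.2, size=4)
    cols["case_same"] = base
    cols["case_rev"] = base[::-1]
    data = pd.DataFrame(cols, index=["g1", "g2", "g3", "g4"])
    return ExpressionMatrix(data, dataset_id="tiny")


@pytest.fixture
def tiny_phenotypes():
    return PhenotypeTable(
        {
            "ctl0": "control",
            "ctl1": "control",
            "ctl2": "control",
            "ctl3": "control",
            "case_same": "I",
            "case_rev": "I",
        }
    )


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        [GeneSet("SETA", "all four genes", ["g1", "g2", "g3", "g4"])],
        source_label="tiny",
    )
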