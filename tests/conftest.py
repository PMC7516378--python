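import numpy as np
import pandas as pd
import pytest

from tfregnet.containers import CandidateNetwork, ExpressionMatrix, FValueMatrix
from tfregnet.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def two_subtype_cohort():
    """Small cohort with planted subtype-specific edges (shared across tests)."""
    return simulate_cohort(
        n_tfs=4,
        n_genes=15,
        subtypes=("A", "B"),
        samples_per_subtype=60,
        edge_density=0.4,
        frac_signature_edges=0.3,
        noise_sd=0.1,
        seed=101,
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    """Single-subtype cohort for parameter-recovery checks."""
    return simulate_cohort(
        n_tfs=5,
        n_genes=20,
        subtypes=("A",),
        samples_per_subtype=200,
        edge_density=0.3,
        frac_signature_edges=0.0,
        noise_sd=0.1,
        seed=11,
    )


@pytest.fixture
def tiny_fvals():
    """Hand-built F matrix: one TF chain A->B->C plus a leaf gene."""
    idx = pd.MultiIndex.from_tuples(
        [("A", "B"), ("B", "C"), ("C", "g1")], names=["tf", "gene"]
    )
    return FValueMatrix(
        f=pd.Series([4.0, 0.5, 2.0], index=idx),
        basal=pd.Series({"B": 10.0, "C": 5.0, "g1": 3.0}),
    )


def make_expression(values: dict, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    if samples is not None:
        df.columns = samples
    return ExpressionMatrix(df.astype(float))


def backbone_of(truth) -> CandidateNetwork:
    return CandidateNetwork(edges=set(truth.backbone))
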