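import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mircoop.datamodel import ClinicalTable, ExpressionMatrix
from mircoop.syndata import SyntheticConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values, features=None, samples=None, centered=False) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    features = features or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=features, columns=samples), centered=centered
    )


def make_clinical(sample_ids, times, events, tnbc=None) -> ClinicalTable:
    n = len(sample_ids)
    tnbc = [True] * n if tnbc is None else list(tnbc)
    return ClinicalTable(
        pd.DataFrame(
            {
                "os_time_months": list(times),
                "os_event": list(events),
                "er": ["neg" if f else "pos" for f in tnbc],
                "pr": ["neg"] * n,
                "her2": ["neg"] * n,
            },
            index=pd.Index(list(sample_ids), name="sample_id"),
        )
    )


@pytest.fixture
def lean_config():
    """A small-but-complete generator config for fast recovery tests."""
    return SyntheticConfig(
        n_genes=40,
        n_pathway_genes=5,
        n_de_genes=10,
        n_cna_genes=5,
        n_mutation_genes=5,
        n_mirnas=20,
        seed=0,
    )


@pytest.fixture
def twelve_sample_surv():
    """A 12-sample survival fixture with ties, censoring and mixed groups."""
    times = np.array([3.0, 5.0, 5.0, 8.0, 10.0, 12.0, 2.0, 5.0, 7.0, 9.0, 12.0, 15.0])
    events = np.array([1, 1, 0, 1, 0, 1, 1, 1, 1, 0, 1, 0])
    labels = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    return labels, times, events
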