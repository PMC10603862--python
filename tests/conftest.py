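from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from semflow.builtin import bootstrap
from semflow.synth import (
    CountsSpec,
    counts_to_csv,
    make_count_matrix,
    make_heartlike_table,
    make_parkinsonlike_table,
    table_to_csv,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_env():
    """Fresh knowledge space with the nine default services registered."""
    return bootstrap()


@pytest.fixture
def scrna_env():
    """Default services plus the single-cell extension set."""
    return bootstrap(single_cell=True)


@pytest.fixture(scope="session")
def heart_table():
    return make_heartlike_table(335, seed=1)


@pytest.fixture(scope="session")
def heart_csv(tmp_path_factory, heart_table):
    path = tmp_path_factory.mktemp("data") / "heart.csv"
    path.write_text(table_to_csv(heart_table[0]))
    return path


@pytest.fixture(scope="session")
def parkinson_csv(tmp_path_factory):
    table, _ = make_parkinsonlike_table(300, seed=2)
    path = tmp_path_factory.mktemp("data") / "parkinson.csv"
    path.write_text(table_to_csv(table))
    return path


@pytest.fixture(scope="session")
def counts_fixture():
    return make_count_matrix(CountsSpec(seed=5))


@pytest.fixture(scope="session")
def counts_csv(tmp_path_factory, counts_fixture):
    path = tmp_path_factory.mktemp("data") / "counts.csv"
    path.write_text(counts_to_csv(counts_fixture[0]))
    return path


HEART_REQUEST = {
    "input_kind": "csv_path",
    "domain": "medical",
    "desired_output_kind": "optimized_model",
}

CLUSTER_REQUEST = {
    "input_kind": "counts_csv_path",
    "domain": "single-cell transcriptomics",
    "desired_output_kind": "cluster_labels",
    "params": {"kmeans_clustering": {"k": 3}},
}


@pytest.fixture
def heart_request():
    return dict(HEART_REQUEST)


@pytest.fixture
def cluster_request():
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in CLUSTER_REQUEST.items()}
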