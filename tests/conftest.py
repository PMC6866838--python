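import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from richclubnet import cohort
from richclubnet.connectome import Connectome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_connectome(n: int, edges, lengths=None) -> Connectome:
    """Connectome from a list of (i, j, weight) with optional edge lengths."""
    w = np.zeros((n, n))
    ml = np.zeros((n, n))
    for idx, (i, j, weight) in enumerate(edges):
        w[i, j] = w[j, i] = weight
        ml[i, j] = ml[j, i] = lengths[idx] if lengths is not None else 1.0
    return Connectome(w, ml)


def streamline_frame(rows) -> pd.DataFrame:
    """Streamline table from (subject, i, j, length) tuples (1-based nodes)."""
    return pd.DataFrame(
        rows, columns=["subject_id", "node_i", "node_j", "length_mm"]
    )


@pytest.fixture(scope="session")
def template90():
    return cohort.generate_template(90, 8, seed=101)


@pytest.fixture(scope="session")
def small_template():
    return cohort.generate_template(30, 4, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort used across integration-level tests."""
    cfg = cohort.CohortConfig(
        seed=21, n_control=6, n_svd=8, n_nodes=30, n_hubs=4
    )
    return cohort.generate_cohort(cfg)
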