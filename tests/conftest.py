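"""Shared fixtures: the planted synthetic cohort used across test modules.

Heavy objects (the 40-subject FC cohort) are session-scoped so that planted
recovery, lesion, hippocampal and acceptance tests share one generation
pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import hipponet as hn


@pytest.fixture(scope="session")
def spec() -> hn.SyntheticSpec:
    """Default study conditions with a fixed seed."""
    return hn.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def parcellation(spec):
    return hn.make_parcellation(spec)


@pytest.fixture(scope="session")
def node_table(parcellation):
    return parcellation[0]


@pytest.fixture(scope="session")
def truth(parcellation):
    return parcellation[1]


@pytest.fixture(scope="session")
def cohort_fcs(spec, parcellation):
    """Fisher-z FC matrices for the full 40-subject synthetic cohort."""
    table, truth = parcellation
    return [
        hn.fc_from_timeseries(hn.simulate_subject_timeseries(spec, i, table, truth))
        for i in range(spec.n_subjects)
    ]


@pytest.fixture(scope="session")
def group_cortical_fc(cohort_fcs, node_table):
    """Group-average FC restricted to cortical nodes, negatives excluded."""
    return hn.group_average_fc(cohort_fcs, exclude_negatives=True).submatrix(
        node_table.cortical_ids
    )


@pytest.fixture(scope="session")
def lesion_fcs(cohort_fcs, node_table):
    """Per-subject cortical nonnegative matrices for path-length analyses."""
    cortical = node_table.cortical_ids
    return [fc.submatrix(cortical).thresholded_nonnegative() for fc in cohort_fcs]


def random_symmetric_nonnegative(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dense random nonnegative weight matrix with zero diagonal."""
    w = rng.random((n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
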