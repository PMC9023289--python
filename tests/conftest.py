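"""Shared fixtures: small labeled block fixtures and trained topic models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import topicspot as ts


@pytest.fixture(scope="session")
def block3():
    """Small 3-type reference with private marker blocks."""
    sc, labels = ts.make_block_fixture(
        n_types=3, genes_per_type=10, cells_per_type=40, depth=1500,
        background_genes=50, seed=101,
    )
    return sc, labels


@pytest.fixture(scope="session")
def trained3(block3):
    """Model trained on the marker feature space (the default workflow)."""
    sc, labels = block3
    fs = ts.select_marker_genes(sc, labels, n_top=10)
    norm = ts.normalize_matrix(sc.subset_genes(fs.genes))
    model = ts.train_lda(norm, ts.TopicModelParams(n_topics=3, seed=0, passes=15))
    tables = ts.make_tables(model, labels)
    return model, tables


@pytest.fixture(scope="session")
def block5():
    """5-type reference at the parameter-recovery scale (500 cells, 200 genes)."""
    sc, labels = ts.make_block_fixture(
        n_types=5, genes_per_type=20, cells_per_type=100, depth=2000,
        background_genes=100, seed=11,
    )
    return sc, labels


@pytest.fixture(scope="session")
def trained5(block5):
    sc, labels = block5
    fs = ts.select_marker_genes(sc, labels, n_top=20)
    norm = ts.normalize_matrix(sc.subset_genes(fs.genes))
    model = ts.train_lda(norm, ts.TopicModelParams(n_topics=10, seed=0))
    tables = ts.make_tables(model, labels)
    return model, tables


@pytest.fixture()
def hand_tables():
    """The two-type, two-topic worked example used across modules."""
    T = np.array([[0.7, 0.1], [0.3, 0.9]])  # K x N, types A, B
    Q = np.array([2.0 / 3.0, 1.0 / 3.0])
    C, P = ts.compute_C(T, Q)
    return T, Q, C, P


def make_coords(spot_ids, xy):
    return ts.SpotCoordinates(
        pd.DataFrame({"spot_id": spot_ids, "x": xy[:, 0], "y": xy[:, 1]})
    )
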