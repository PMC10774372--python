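"""Shared fixtures: session-scoped synthetic cohorts reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from mbenkit.expression_core import embed_and_cluster, merge_similar_clusters, normalize
from mbenkit.synthetic import (
    ExpressionConfig,
    TissueConfig,
    cnv_panel,
    default_cnv_blocks,
    default_panel,
    generate_cohort,
    generate_expression,
    generate_tissue,
)


@pytest.fixture(scope="session")
def spatial_panel():
    return default_panel()


@pytest.fixture(scope="session")
def default_tissue():
    """The default single-patient tissue: 2000x2000 um, 3 nodules, 5000 cells."""
    return generate_tissue(TissueConfig(seed=0))


@pytest.fixture(scope="session")
def cohort(default_tissue, spatial_panel):
    """Default 6-state cohort counts + truth on the spatial panel."""
    adata, truth = generate_expression(
        default_tissue, spatial_panel, ExpressionConfig(seed=1)
    )
    return adata, truth


@pytest.fixture(scope="session")
def cohort_clusters(cohort):
    """Normalized matrix plus the merged Louvain partition of the cohort."""
    adata, _ = cohort
    norm = normalize(adata)
    clusters = merge_similar_clusters(embed_and_cluster(norm, seed=0), norm)
    return norm, clusters


@pytest.fixture(scope="session")
def majority_state(cohort, cohort_clusters):
    """Majority true state per recovered cluster."""
    adata, _ = cohort
    _, clusters = cohort_clusters
    return adata.obs["state"].groupby(clusters.labels).agg(lambda s: s.mode()[0])


@pytest.fixture(scope="session")
def cnv_cohort():
    """Two-patient genome-wide cohort with the planted 1.5x / 300-gene gain."""
    cfg = TissueConfig(
        n_cells=1000, field_width=900, field_height=900,
        nodule_radius_mean=150, nodule_radius_sd=15, seed=3,
    )
    tissues = generate_cohort(cfg, patients=("P1", "P2"))
    panel = cnv_panel()
    adata, truth = generate_expression(
        tissues, panel, ExpressionConfig(seed=4, cnv_blocks=default_cnv_blocks("P1"))
    )
    return adata, truth, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
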