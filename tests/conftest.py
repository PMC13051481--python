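"""Shared fixtures: run configuration, synthetic cells and a small
segmented dataset, generated programmatically (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

from gliamorph import synthetic as S
from gliamorph.config import RunConfig


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def ramified_cell():
    return S.simulate_cell(S.ShapeParams(soma_radius=12, n_primary_branches=5), seed=11)


@pytest.fixture(scope="session")
def disk_cell():
    """Pure-disk cell (no branches): amoeboid limit."""
    return S.simulate_cell(
        S.ShapeParams(soma_radius=20, n_primary_branches=0, image_size=96),
        seed=3,
        plane_noise=0.0,
    )


@pytest.fixture(scope="session")
def mixed_panel():
    return [
        S.GeneModel("proc_hi", 40, 3.0),
        S.GeneModel("soma_hi", 40, -3.0),
        S.GeneModel("neutral_a", 40, 0.0),
        S.GeneModel("neutral_b", 40, 0.0),
        S.GeneModel(
            "pair_x", 30, -1.0, cluster_sigma=1.0, cluster_children=8, coloc_partner="pair_y"
        ),
        S.GeneModel(
            "pair_y", 30, -1.0, cluster_sigma=1.0, cluster_children=8, coloc_partner="pair_x"
        ),
    ]


@pytest.fixture(scope="session")
def small_dataset(cfg, mixed_panel):
    """Nine-cell tiled field with an astrocyte blob per cell."""
    astro = [S.GeneModel("astro_gene", 50, 0.0)]
    return S.simulate_dataset(
        cfg,
        9,
        mixed_panel,
        seed=21,
        astrocyte_genes=astro,
        astrocyte_fraction=0.3,
    )


@pytest.fixture(scope="session")
def segmented(small_dataset):
    from gliamorph import segmentation as seg

    cells, counts, labeled = seg.segment_field(
        small_dataset.stack,
        small_dataset.boundaries,
        small_dataset.transcripts,
        small_dataset.boundaries.annotations,
    )
    return cells, counts, labeled
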