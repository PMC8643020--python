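import logging

import numpy as np
import pandas as pd
import pytest

from scregmark.datatypes import ExpressionMatrix
from scregmark.pipeline import PipelineConfig, run_pipeline
from scregmark.synthetic import generate_all

logging.getLogger("scregmark").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: 6 samples x 200 cells, 1500 genes,
    4 planted types, plus regulation pairs, bulk matrix and survival."""
    return generate_all(seed=1)


@pytest.fixture(scope="session")
def pipeline_run(default_fixture, tmp_path_factory):
    """One full pipeline run on the default fixture (seed 7)."""
    expr, reg, bulk, kggs, surv, truths = default_fixture
    out = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(out_dir=str(out), seed=7)
    result = run_pipeline(
        cfg, expression=expr, regulation=reg, kggs=kggs, bulk=bulk, survival=surv
    )
    return cfg, result


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 cells over two samples, handy for reader/filter tests."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        values=np.array(
            [[0.0, 1.0, 2.0, 3.0], [5.0, 0.0, 1.0, 0.0], [2.0, 2.0, 2.0, 2.0]]
        ),
        cell_sample={"c1": "S1", "c2": "S1", "c3": "S2", "c4": "S2"},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
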