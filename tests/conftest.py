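import dataclasses

import numpy as np
import pandas as pd
import pytest

from stcoloc.io import Circle
from stcoloc.simulate import SimulationConfig
from stcoloc.study import ReplicateResult, run_replicate


@pytest.fixture(scope="session")
def default_replicate() -> ReplicateResult:
    """One full pipeline run at the default study conditions (seed 0)."""
    return run_replicate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down configuration for fast structural tests."""
    base = SimulationConfig()
    regions = (
        dataclasses.replace(base.regions[0], circle=Circle(300.0, 300.0, 250.0)),
        dataclasses.replace(base.regions[1], circle=Circle(850.0, 650.0, 250.0)),
    )
    return SimulationConfig(seed=11, grid_rows=12, grid_cols=12, n_genes=400, markers_per_cluster=15, regions=regions)


def make_scores(rows: dict[str, dict[str, float]]):
    """Helper: a ScoreMatrix from {barcode: {cluster: score}} dicts."""
    from stcoloc.deconvolution import ScoreMatrix

    df = pd.DataFrame(rows).T.fillna(0.0)
    assigned = df.sum(axis=1) > 0
    df = df.div(df.sum(axis=1).replace(0, 1.0), axis=0)
    return ScoreMatrix(
        scores=df,
        assigned=pd.Series(assigned, index=df.index),
        residual=pd.Series(0.0, index=df.index),
    )


@pytest.fixture
def scores_factory():
    return make_scores


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
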