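"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cellvar as cv


def single_condition_config(
    n_genes: int = 800, n_cells: int = 300, seed: int = 0, **overrides
) -> cv.SimulationConfig:
    """A minimal one-condition, one-batch configuration with no planted
    structure beyond HVGs — handy for estimator-level checks."""
    params = dict(
        n_genes=n_genes,
        conditions=("serum",),
        n_cells_per_condition={"serum": n_cells},
        n_batches_per_condition={"serum": 1},
        subpop_spec={"serum": [cv.SubpopSpec("ground", 1.0)]},
        g2m_fraction={"serum": 0.5},
        twoc_proportion={},
        content_by_condition={},
        qc_low_depth_fraction=0.0,
        qc_high_mito_fraction=0.0,
        qc_capture_bad_fraction=0.0,
        seed=seed,
    )
    params.update(overrides)
    return cv.SimulationConfig(**params)


@pytest.fixture(scope="session")
def full_dataset():
    """Full three-condition dataset at reduced size, with QC failures."""
    cfg = cv.SimulationConfig(n_genes=1000, seed=42)
    return cv.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def full_normalized(full_dataset):
    """(obs of QC-passing cells, raw counts, normalized, batch-adjusted)."""
    obs = full_dataset.obs[full_dataset.obs["qc_fate"] == "pass"]
    counts = cv.counts_frame(full_dataset)[obs.index]
    s = cv.size_factors(counts, spike_mask=full_dataset.var["is_spike"])
    norm = cv.normalize(counts, s)
    adj = cv.batch_adjust(norm, obs["batch"], obs["condition"])
    return obs, counts, norm, adj


@pytest.fixture(scope="session")
def simple_dataset():
    return cv.simulate_dataset(single_condition_config(seed=3))


@pytest.fixture(scope="session")
def simple_normalized(simple_dataset):
    counts = cv.counts_frame(simple_dataset)
    s = cv.size_factors(counts, spike_mask=simple_dataset.var["is_spike"])
    norm = cv.normalize(counts, s)
    endog = norm.loc[~simple_dataset.var["is_spike"].values]
    return counts, norm, endog
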