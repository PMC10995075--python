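"""Shared fixtures: small rendered datasets and a fitted SPR/global pair.

The heavier fixtures are session-scoped so the rendered study-design dataset
and the gradient-boosting fits are computed once and shared between the unit
suite and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from kidneystrip import evaluation, spr, synthdata


@pytest.fixture(scope="session")
def study_dataset():
    """22-minute slice of the study design (65 concentrations x 3 replicates),
    preprocessed and featurized as HOC/LAB: 195 captures -> 780 tiles."""
    records = synthdata.generate_captures(replicates=3, time_points=(22,), seed=11)
    return evaluation.dataset_from_captures(records)


@pytest.fixture(scope="session")
def capture_split(study_dataset):
    """Deterministic capture-grouped 75/25 split of the study dataset."""
    caps = np.unique(study_dataset.capture_ids)
    rng = np.random.default_rng(3)
    test_caps = rng.choice(caps, size=len(caps) // 4, replace=False)
    test_mask = np.isin(study_dataset.capture_ids, test_caps)
    return ~test_mask, test_mask


@pytest.fixture(scope="session")
def fitted_hbt_pair(study_dataset, capture_split):
    """A 4-bin HBT SPR model and its matched global HBT regressor, both fitted
    on the training side of the capture split with the same seed."""
    train, _ = capture_split
    partition = spr.PartitionScheme()
    model = spr.fit(
        study_dataset.X[train],
        study_dataset.concentrations[train],
        partition,
        spr.SubEstimatorSpec("HBT"),
        random_state=0,
    )
    global_reg = spr.make_estimator(spr.SubEstimatorSpec("HBT"), "regressor", 0)
    global_reg.fit(study_dataset.X[train], study_dataset.concentrations[train])
    return model, global_reg


@pytest.fixture(scope="session")
def tiny_tiled_dataset():
    """A small rendered-and-featurized dataset (coarse grid, 22 min) for
    evaluation-harness tests where fitting speed matters."""
    grid = synthdata.build_concentration_grid([(0, 4, 0.5), (5, 20, 3), (30, 60, 15)])
    records = synthdata.generate_captures(grid, replicates=3, time_points=(22,), seed=2)
    return evaluation.dataset_from_captures(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
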