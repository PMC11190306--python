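"""Shared fixtures: a reduced-size synthetic cohort and one trained network.

The smoke cohort keeps the study's class ratio (healthy : grade2 : grade3 :
grade4 = 265 : 150 : 78 : 150, scaled to 82 tubers) on a 64-point grid so
network training stays affordable in a test run.
"""

import numpy as np
import pytest

from spudnet import (
    NoiseModel,
    SimulationConfig,
    SpectrumSVC,
    SplitSpec,
    augment_gaussian,
    simulate_dataset,
    stratified_split,
)
from spudnet.estimators import ResNet1DClassifier

SMOKE_COMPOSITION = (34, 19, 10, 19)


@pytest.fixture(scope="session")
def smoke_config():
    return SimulationConfig(n_points=64, composition=SMOKE_COMPOSITION, seed=0)


@pytest.fixture(scope="session")
def smoke_dataset(smoke_config):
    return simulate_dataset(smoke_config)


@pytest.fixture(scope="session")
def smoke_augmented(smoke_dataset):
    return augment_gaussian(smoke_dataset, NoiseModel(seed=0))


@pytest.fixture(scope="session")
def smoke_split(smoke_augmented):
    return stratified_split(smoke_augmented, SplitSpec(seed=0))


@pytest.fixture(scope="session")
def trained_modified(smoke_augmented, smoke_split):
    """Modified network fit on the smoke cohort's calibration view."""
    ds, split = smoke_augmented, smoke_split
    clf = ResNet1DClassifier(
        variant="modified", epochs=10, batch_size=64, random_state=0
    )
    clf.fit(ds.intensities[split.calibration], ds.grades[split.calibration])
    return clf


@pytest.fixture(scope="session")
def fitted_svm(smoke_augmented, smoke_split):
    ds, split = smoke_augmented, smoke_split
    return SpectrumSVC().fit(
        ds.intensities[split.calibration], ds.grades[split.calibration]
    )
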