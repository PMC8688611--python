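import numpy as np
import pytest

from actlc.decay_chain import ac225_chain
from actlc.equilibrium_prediction import (
    build_modeling_frame,
    fit_glm,
    split_sets,
)
from actlc.synthetic_study import generate_observations
from actlc.tlc_plate_model import DetectionModel, DevelopmentModel


@pytest.fixture(scope="session")
def chain():
    return ac225_chain()


@pytest.fixture(scope="session")
def chain_full():
    """Full chain without prompt collapse (At-217 and Po-213 explicit)."""
    return ac225_chain(prompt_threshold_h=0.0)


@pytest.fixture(scope="session")
def det():
    return DetectionModel.default()


@pytest.fixture(scope="session")
def dev():
    return DevelopmentModel()


@pytest.fixture(scope="session")
def observations_seed1():
    return generate_observations(seed=1)


@pytest.fixture(scope="session")
def frame_seed1(observations_seed1):
    return build_modeling_frame(observations_seed1)


@pytest.fixture(scope="session")
def split_seed1(frame_seed1):
    return split_sets(list(frame_seed1["set_id"].unique()), seed=1)


@pytest.fixture(scope="session")
def training_frame_seed1(frame_seed1, split_seed1):
    train_ids, _ = split_seed1
    return frame_seed1[frame_seed1["set_id"].isin(train_ids)]


@pytest.fixture(scope="session")
def validation_frame_seed1(frame_seed1, split_seed1):
    _, val_ids = split_seed1
    return frame_seed1[frame_seed1["set_id"].isin(val_ids)]


@pytest.fixture(scope="session")
def fit_seed1(training_frame_seed1):
    return fit_glm(training_frame_seed1)
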