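"""Shared fixtures.

Heavy artifacts (trained desk-profile DDPM, classifier training sets) are
session-scoped so acceptance tests can share them within the time budget.
"""

import numpy as np
import pytest

from postfocus import synth


# a small, fast scene profile used across unit tests: 64 px images rendered
# directly at a coarser pixel pitch so no resizing is needed downstream
SMALL_SCENE = synth.SceneSpec(image_size_px=64, pixel_pitch_um=0.83,
                              n_cells=2, radius_um_range=(4.0, 6.0))
SMALL_MODEL = synth.DefocusModel(sigma_per_um=0.35)


@pytest.fixture(scope="session")
def small_scene():
    return SMALL_SCENE


@pytest.fixture(scope="session")
def small_model():
    return SMALL_MODEL


@pytest.fixture(scope="session")
def small_pair_dataset():
    return synth.make_pair_dataset(SMALL_SCENE, SMALL_MODEL, n_pairs=48,
                                   identity_fraction=0.25, offsets_um=(5.0, 10.0),
                                   seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
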