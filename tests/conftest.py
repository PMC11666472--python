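import numpy as np
import pytest

from sentencode import build_design, enumerate_pool, load_lexicon
from sentencode.simulate import Blob, GroundTruth, VoxelGrid, generate_dataset


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def pool(lexicon):
    return enumerate_pool(list(lexicon.nouns), list(lexicon.verbs))


@pytest.fixture(scope="session")
def design():
    """Full 6-run balanced stimulus design, fixed seed."""
    return build_design(seed=20_001)


@pytest.fixture(scope="session")
def production_sentences(design):
    return [s for s in design.sentences if s.trial_type == "production"]


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid.box((12, 12, 12), voxel_size_mm=2.5)


@pytest.fixture(scope="session")
def planted_dataset(design, production_sentences, small_grid):
    """Two-blob dataset (narrow_roles + bag_of_verbs signal) at SNR 2 with
    realistic attrition and sentence substitution; 4 participants."""
    truth = GroundTruth.plant_blobs(
        small_grid,
        [Blob((3, 3, 3), 2.0, "narrow_roles"), Blob((8, 8, 8), 2.0, "bag_of_verbs")],
        production_sentences,
        signal_amplitude=2.0,
        noise_sd=1.0,
        seed=7,
    )
    return generate_dataset(
        design,
        truth,
        n_participants=4,
        attrition_rate=0.07,
        substitution_rate=0.23,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_dataset(design, production_sentences, small_grid):
    """Pure-noise dataset (no planted voxels), 4 participants."""
    truth = GroundTruth.plant_blobs(
        small_grid, [], production_sentences, noise_sd=1.0, seed=5
    )
    return generate_dataset(design, truth, n_participants=4, seed=13)
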