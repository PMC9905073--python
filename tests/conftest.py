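"""Shared fixtures: toy structures and trained scaled-down models.

The trainable fixtures use reduced study conditions (see docs/methods.md):
a coarse box of 13 voxels at 0.50 A and a fine box of 23 voxels at
0.25 A — both half-edges exceed the 2.8 A hydration distance of the
synthetic placement rule — and a narrow Model-6-shaped network.
"""

from __future__ import annotations

import numpy as np
import pytest

import hydrosite as hs

#: Scaled-down boxes used by the trainable fixtures.
COARSE_TEST_BOX = hs.BoxSpec(13, 0.50)
FINE_TEST_BOX = hs.BoxSpec(23, 0.25)


@pytest.fixture(scope="session")
def toy_structure() -> hs.ProteinStructure:
    """One deterministic synthetic structure with ASA and rule waters."""
    return hs.generate_structure(hs.ToyStructureSpec(seed=42))


@pytest.fixture(scope="session")
def training_corpus() -> list[hs.ProteinStructure]:
    """Synthetic corpus for classifier training."""
    return hs.generate_corpus(62, hs.ToyStructureSpec(), seed=11)


@pytest.fixture(scope="session")
def heldout_structure() -> hs.ProteinStructure:
    """A structure outside the training corpus, for end-to-end recovery."""
    return hs.generate_structure(hs.ToyStructureSpec(seed=90001))


@pytest.fixture(scope="session")
def coarse_split(training_corpus):
    ds = hs.build_dataset(training_corpus, COARSE_TEST_BOX, seed=11)
    return hs.split_dataset(ds, 0.7, seed=11)


@pytest.fixture(scope="session")
def trained_coarse_model(coarse_split) -> hs.HydrationCNN:
    """Narrow Model-6-shaped coarse classifier trained on the corpus."""
    Xt, yt = coarse_split.train.to_arrays()
    Xv, yv = coarse_split.validation.to_arrays()
    model = hs.HydrationCNN(
        channels=8, fcb_nodes=16, conv_layers_per_unit=1, input_edge=13,
        epochs=40, batch_size=128, learning_rate=2e-3, random_state=7,
        box=COARSE_TEST_BOX, resolution_tag="coarse",
    )
    return model.fit(Xt, yt, validation=(Xv, yv))


@pytest.fixture(scope="session")
def trained_fine_model(training_corpus) -> hs.HydrationCNN:
    """Narrow fine-resolution classifier trained on the corpus."""
    ds = hs.build_dataset(training_corpus, FINE_TEST_BOX, seed=12)
    split = hs.split_dataset(ds, 0.7, seed=12)
    Xt, yt = split.train.to_arrays()
    model = hs.HydrationCNN(
        channels=8, fcb_nodes=32, conv_layers_per_unit=1, input_edge=23,
        epochs=15, batch_size=128, learning_rate=2e-3, dropout_rate=0.1,
        random_state=7, box=FINE_TEST_BOX, resolution_tag="fine",
    )
    return model.fit(Xt, yt)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
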