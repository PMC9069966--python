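"""Shared fixtures: a small synthetic dataset and a revised corpus.

Session scope keeps the expensive train+revise work to a single run across
the whole suite.
"""

import pytest

from cerebra.fgrep import FgrepConfig, revise_corpus
from cerebra.network import TrainingConfig
from cerebra.synthetic import SynthesisConfig, make_dataset


@pytest.fixture(scope="session")
def small_config():
    return SynthesisConfig(
        n_words=12, n_sentences=8, n_voxels=50, n_subjects=1,
        n_repetitions=4, hidden_dim=24, n_raters=6, seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_dataset(small_config)


@pytest.fixture(scope="session")
def small_revised(small_dataset):
    return revise_corpus(
        small_dataset.sentences, small_dataset.lexicon, small_dataset.fmri,
        train_config=TrainingConfig(max_epochs=300, target_mse=1e-3, seed=0),
        fgrep_config=FgrepConfig(max_iters=300),
        n_runs=1, base_seed=0,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size default fixture (40 words, 30 sentences, 396 voxels)."""
    return make_dataset(SynthesisConfig(seed=0))
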