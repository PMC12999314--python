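import numpy as np
import pytest

from ppifern.featurize import feature_matrix, featurize_dataset
from ppifern.model import PipelineConfig
from ppifern.sdae import SDAEConfig
from ppifern.synthetic import SynthConfig, generate_dataset


def eval_pipeline_config(seed: int = 11, with_sdae: bool = True) -> PipelineConfig:
    """The reduced-cost pipeline configuration used for end-to-end checks:
    a small encoder trained long enough for the planted signal to reach the
    classifier."""
    return PipelineConfig(
        sdae=SDAEConfig(
            layer_dims=(128, 64),
            epochs_pretrain=10,
            epochs_finetune=300,
            learning_rate=1.0,
        ),
        with_sdae=with_sdae,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset for plumbing tests (not for accuracy bars)."""
    return generate_dataset(SynthConfig(n_proteins=40, n_pairs=120, seed=3))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    vectors = featurize_dataset(small_dataset.pairs, small_dataset.pssms)
    return feature_matrix(vectors)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 200 proteins, 1000 balanced pairs,
    signal 3.0, noise 1.0."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    vectors = featurize_dataset(default_dataset.pairs, default_dataset.pssms)
    return feature_matrix(vectors)
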