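"""Shared fixtures: miniature cohorts and model configurations.

Unit tests run on deliberately tiny geometries (32x40 frames, short
encoding windows) so that full train/evaluate cycles stay in the
seconds range; the acceptance suite uses the full desk-scale protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mcpdnet import synthetic as syn
from mcpdnet.preprocessing import EncodingSpec, build_cohort_dataset

TINY_H, TINY_W = 32, 40
TINY_SPEC = EncodingSpec(intervals=(2, 5, 10), fps=8.0)


def make_tiny_dataset(n_pairs=2, duration=20.0, seed=0, stride=4):
    """A miniature paired dataset: small frames, short windows."""
    params = syn.CohortParams(duration=duration)
    profiles, seqs = syn.simulate_cohort(n_pairs, params, seed, TINY_H, TINY_W)
    manifest = pd.DataFrame(
        [{"subject_id": p.subject_id, "pair_id": p.pair_id, "label": p.label} for p in profiles]
    )
    return build_cohort_dataset(manifest, seqs, TINY_SPEC, stride=stride)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def tiny_sample(tiny_dataset):
    return tiny_dataset[0]


@pytest.fixture(scope="session")
def tiny_model_config(tiny_sample):
    from mcpdnet.models import ModelConfig

    return ModelConfig.from_sample(tiny_sample, seed=0)


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """One trained bimodal model on the miniature dataset (shared)."""
    from mcpdnet.training import TrainConfig, train

    train_set = [s for s in tiny_dataset if s.pair_id == 0]
    return train(train_set, TrainConfig(seed=0, variant="MCPDNet"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
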