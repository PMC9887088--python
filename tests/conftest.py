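"""Shared fixtures: synthetic embedding datasets and trained models.

Everything is generated programmatically and seeded; the expensive trained
models are session-scoped so unit and acceptance tests share one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from remhom import (
    LabelSpace,
    MLPConfig,
    SyntheticConfig,
    align_to_labels,
    make_synthetic,
    train_mlp,
)
from remhom.embeddings import FeatureMatrix

# Study conditions for the separable-recovery scenario: 20 named classes plus
# a mixed-bag "other" the size of one named class, 64-dim embeddings,
# 100 members per class, inter-centroid distance 8 within-class sigmas.
SEPARABLE_CONFIG = SyntheticConfig(
    n_classes=20, dim=64, n_per_class=100, separation=8.0,
    other_fraction=0.05, seed=1,
)
NULL_CONFIG = SyntheticConfig(
    n_classes=20, dim=64, n_per_class=100, separation=0.0,
    other_fraction=0.05, seed=1,
)
SPLIT_SEED = 1


def synthetic_feature_matrix(config: SyntheticConfig):
    store, records = make_synthetic(config)
    named = sorted({r.superfamily for r in records if r.superfamily != "other"})
    label_space = LabelSpace(tuple(named), has_other=True)
    return align_to_labels(store, records, label_space)


def train_val_test_split(fm: FeatureMatrix, seed: int = SPLIT_SEED,
                         fractions=(0.6, 0.2, 0.2)):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(fm.n)
    n_tr = int(fractions[0] * fm.n)
    n_va = int(fractions[1] * fm.n)
    parts = (idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:])
    return tuple(
        FeatureMatrix(fm.X[p], fm.y[p], [fm.ids[j] for j in p], fm.label_space)
        for p in parts
    )


def nearest_centroid_accuracy(train: FeatureMatrix, test: FeatureMatrix) -> float:
    """Independent oracle: classify by closest per-class training centroid."""
    K = len(train.label_space)
    centroids = np.stack([train.X[train.y == k].mean(axis=0) for k in range(K)])
    d2 = ((test.X[:, None, :] - centroids[None]) ** 2).sum(axis=-1)
    return float(np.mean(d2.argmin(axis=1) == test.y))


@pytest.fixture(scope="session")
def separable_splits():
    fm = synthetic_feature_matrix(SEPARABLE_CONFIG)
    return train_val_test_split(fm)


@pytest.fixture(scope="session")
def null_splits():
    fm = synthetic_feature_matrix(NULL_CONFIG)
    return train_val_test_split(fm)


@pytest.fixture(scope="session")
def separable_mlp(separable_splits):
    train, val, _ = separable_splits
    return train_mlp(train, val, MLPConfig(seed=1))
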