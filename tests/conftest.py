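import numpy as np
import pytest

from accelhar import SyntheticConfig, generate_cohort, build_dataset
from accelhar.features import N_FEATURES, FeatureDataset
from accelhar.signal_io import ACTIVITIES, Clip


def make_clip(data: np.ndarray, activity: str = "walk", **kw) -> Clip:
    defaults = dict(subject_id="s01", context="lab", start=0.0, sample_rate_hz=100.0)
    defaults.update(kw)
    return Clip(activity=activity, data=np.asarray(data, dtype=float), **defaults)


def random_clip(rng: np.random.Generator, n: int = 1000, scale: float = 1.0) -> Clip:
    return make_clip(scale * rng.normal(size=(3, n)))


def embed_features(block: np.ndarray, labels, subjects=None, contexts=None) -> FeatureDataset:
    """Place a small informative block into the first columns of an
    otherwise-zero 178-wide feature matrix."""
    block = np.atleast_2d(np.asarray(block, dtype=float))
    m = block.shape[0]
    matrix = np.zeros((m, N_FEATURES))
    matrix[:, : block.shape[1]] = block
    return FeatureDataset(
        matrix,
        list(labels),
        list(subjects) if subjects is not None else [f"s{i % 3}" for i in range(m)],
        list(contexts) if contexts is not None else ["lab"] * m,
    )


def two_cluster_dataset(n_per_class: int = 20, spread: float = 0.05, seed: int = 0,
                        centers=((0.0, 0.0), (5.0, 5.0)), classes=("sit", "walk")):
    """Well-separated Gaussian clusters, linearly separable by a margin."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for center, cls in zip(centers, classes):
        blocks.append(np.asarray(center) + spread * rng.normal(size=(n_per_class, len(center))))
        labels += [cls] * n_per_class
    return embed_features(np.vstack(blocks), labels)


@pytest.fixture(scope="session")
def tiny_config():
    return SyntheticConfig(
        n_subjects=2,
        clips_per_activity_lab=4,
        clips_per_activity_home=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_datasets(tiny_cohort):
    return build_dataset(tiny_cohort.lab), build_dataset(tiny_cohort.home)
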