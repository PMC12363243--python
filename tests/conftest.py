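import numpy as np
import pytest

from ecophase import synthetic_data as sd
from ecophase import tetra_features as tf


def random_read(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    alphabet = "ACGTN"
    probs = [(1 - n_prob) / 4] * 4 + [n_prob]
    return "".join(rng.choice(list(alphabet), p=probs) for _ in range(length))


def random_reads(rng: np.random.Generator, n: int, length: int, n_prob: float = 0.0) -> list[str]:
    codes = rng.choice(5, size=(n, length), p=[(1 - n_prob) / 4] * 4 + [n_prob])
    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return [bytes(alphabet[row]).decode() for row in codes]


@pytest.fixture(scope="session")
def index():
    return tf.build_canonical_index()


def build_cohort_features(separation: float, seed: int, n_groups: int = 5, samples: int = 40):
    """Simulate a cohort and return (feature DataFrame, labels, cohort)."""
    models = sd.make_ecosystem_models(n_groups, separation, seed=seed)
    cohort = sd.SyntheticCohort(
        models=models, samples_per_group=samples, separation=separation, seed=seed
    )
    idx = tf.build_canonical_index()
    profiles, labels = [], []
    for sid, gk, reads in sd.cohort_reads(cohort):
        profiles.append(tf.count_tetramers(reads, idx, sid))
        labels.append(gk)
    return tf.feature_matrix(profiles), labels, cohort


@pytest.fixture(scope="session")
def recovery_cohort():
    """The study-condition cohort: 5 ecosystem groups x 40 samples at the
    default separation, fixed seed."""
    return build_cohort_features(sd.DEFAULT_SEPARATION, seed=42)
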