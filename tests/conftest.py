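import numpy as np
import pytest

from polydca import (
    BinarySplit,
    ConfusionAtThreshold,
    cumulative_splits,
    default_generator_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def synthetic_cohort():
    """A seeded 2000-subject cohort with its true probability matrix."""
    return generate_cohort(default_generator_spec(n=2000, seed=42))


@pytest.fixture(scope="session")
def severe_any_splits(synthetic_cohort):
    """(severe, any) cumulative splits of the synthetic cohort under the truth."""
    cohort, truth = synthetic_cohort
    splits = cumulative_splits(truth, cohort)
    return splits[1], splits[0]


@pytest.fixture()
def perfect_split():
    """Risks perfectly separate labels: all positives above all negatives."""
    risks = np.concatenate([np.full(40, 0.9), np.full(60, 0.1)])
    labels = np.concatenate([np.ones(40, dtype=int), np.zeros(60, dtype=int)])
    return BinarySplit(
        name="perfect", positive_categories=(1,), risks=risks, labels=labels
    )


def random_confusion(rng: np.random.Generator) -> ConfusionAtThreshold:
    """A random confusion table with positive prevalence and r in [0, 1)."""
    tp, fn = int(rng.integers(1, 50)), int(rng.integers(0, 50))
    fp, tn = int(rng.integers(0, 50)), int(rng.integers(0, 50))
    r = float(rng.uniform(0.0, 0.95))
    return ConfusionAtThreshold(r=r, TP=tp, FP=fp, TN=tn, FN=fn)
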