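import numpy as np
import pytest

from abrcog.scoring import build_cognitive_scores
from abrcog.synthetic import default_params, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """A study-sized (n=118) default synthetic cohort plus its truth."""
    return generate_cohort(default_params(seed=42))


@pytest.fixture(scope="session")
def scored_cohort(study_cohort):
    table, _ = study_cohort
    return build_cognitive_scores(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney AUC, ties worth 1/2 (independent oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    good = scores[labels]
    poor = scores[~labels]
    total = 0.0
    for g in good:
        for p in poor:
            if g > p:
                total += 1.0
            elif g == p:
                total += 0.5
    return total / (good.size * poor.size)
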