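import numpy as np
import pytest

from flychoice.trial_io import CohortDataset, FlyRecord


def make_cohort(group_counts, n_trials=40):
    """Build a CohortDataset from {label: [n_toward per fly]} directly."""
    flies = []
    labels = list(group_counts.keys())
    for g, towards in group_counts.items():
        for i, t in enumerate(towards):
            flies.append(
                FlyRecord(fly_id=f"{g}-{i}", group_label=g, n_trials=n_trials,
                          n_toward=int(t), lane_id=f"L{i % 4}")
            )
    return CohortDataset(flies=flies, excluded=[], group_labels=labels,
                         required_trials=n_trials)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_cohort():
    """Two small groups with distinct means, 40 trials per fly."""
    return make_cohort({
        "A": [30, 28, 32, 29, 31, 30, 27, 33],
        "B": [20, 22, 18, 21, 19, 20, 23, 17],
    })
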