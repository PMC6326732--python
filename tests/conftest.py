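import numpy as np
import pandas as pd
import pytest

from cyclicity import CohortSpec, cohort_features, gen_cohort
from cyclicity.features import CohortFeatures


@pytest.fixture(scope="session")
def small_cohort_records():
    """Tiny two-group cohort: 4+5 subjects, 8 channels, 2 sessions x 2 runs."""
    spec = CohortSpec(
        n_group_a=4, n_group_b=5, n_channels=8, n_samples=160, n_periods=4,
        ordering_jitter_a=0.05, ordering_jitter_b=0.4, subject_jitter=0.5,
        seed=42,
    )
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort_records):
    return cohort_features(small_cohort_records)


def make_feature_table(X, groups, runs_per_subject=1):
    """CohortFeatures from a plain matrix: one subject per runs_per_subject rows."""
    n = X.shape[0]
    n_sub = n // runs_per_subject
    rows = []
    for s in range(n_sub):
        for r in range(runs_per_subject):
            rows.append(
                {
                    "subject": f"s{s:03d}",
                    "group": groups[s * runs_per_subject],
                    "session": 1 + r // max(1, runs_per_subject // 2),
                    "run": 1 + r % max(1, runs_per_subject // 2),
                }
            )
    pairs = [(f"p{i}", f"q{i}") for i in range(X.shape[1])]
    return CohortFeatures(pd.DataFrame(rows), np.asarray(X, float), pairs)
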