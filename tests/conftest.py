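import numpy as np
import pytest

from forceskill.force_data import Cohort, ForceTrace, TrialRecord


def make_separable_trials(n_expert: int, n_novice: int, length: int = 300,
                          seed: int = 7) -> list[TrialRecord]:
    """Perfectly separated toy trials: experts hover near 1 N, novices near 5 N."""
    rng = np.random.default_rng(seed)
    recs = []
    for k in range(n_expert):
        v = np.clip(1.0 + rng.normal(0, 0.2, size=length), 0, 10)
        recs.append(TrialRecord(ForceTrace(v), "E1", "Expert", k + 1))
    for k in range(n_novice):
        v = np.clip(5.0 + rng.normal(0, 0.2, size=length), 0, 10)
        recs.append(TrialRecord(ForceTrace(v), "N1", "Novice", k + 1))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def tiny_cohort():
    """Three-trial cohort with two surgeons and differing trace lengths."""
    rng = np.random.default_rng(0)
    return Cohort(records=[
        TrialRecord(ForceTrace(rng.uniform(0, 8, size=120)), "E1", "Expert", 1),
        TrialRecord(ForceTrace(rng.uniform(0, 8, size=300)), "E1", "Expert", 2),
        TrialRecord(ForceTrace(rng.uniform(0, 8, size=450)), "N1", "Novice", 1),
    ])
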