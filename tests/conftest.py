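import numpy as np
import pytest

import skinrhythm as sr


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def study_cohort():
    """A default-condition simulated cohort (11 subjects x 2 layers x 7 times)."""
    cfg = sr.CohortConfig(seed=5, n_genes=300)
    matrix, records, truth = sr.simulate_cohort(cfg)
    return matrix, records, truth


def record_arrays(records):
    """(times, subject_ids, layer_labels, sample_ids) convenience unpack."""
    t = np.array([r.internal_time_h for r in records], dtype=float)
    subj = [r.subject_id for r in records]
    lay = [r.layer for r in records]
    ids = [r.sample_id for r in records]
    return t, subj, lay, ids
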