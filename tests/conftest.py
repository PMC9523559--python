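import numpy as np
import pandas as pd
import pytest

import mitometab as mm
from mitometab.counts import BASES, AlleleCountTensor


@pytest.fixture(scope="session")
def small_cohort():
    """A clean heteroplasmic cohort used by several read-only tests."""
    cfg = mm.SimulationConfig(
        n_individuals=120,
        n_metabolites=6,
        n_positions=12,
        seed=11,
        homoplasmic_fraction=0.0,
        missing_rate=0.0,
        outlier_rate=0.0,
    )
    return mm.simulate_cohort(cfg)


def tensor_from_planes(ref_base, alt_base, a_counts, b_counts, positions=None):
    """Build a tensor with reads on exactly two bases per position."""
    a_counts = np.asarray(a_counts)
    b_counts = np.asarray(b_counts)
    n, s = a_counts.shape
    if positions is None:
        positions = np.arange(1, s + 1)
    counts = np.zeros((n, s, 4), dtype=np.int64)
    counts[:, :, BASES.index(ref_base)] = a_counts
    counts[:, :, BASES.index(alt_base)] = b_counts
    ids = np.array([f"ind{k:03d}" for k in range(n)])
    return AlleleCountTensor(ids, np.asarray(positions), counts)


def plain_covariates(ids, batch_count=2, contaminated=(), diabetic=()):
    n = len(ids)
    return pd.DataFrame(
        {
            "age": np.linspace(35, 70, n),
            "sex": np.arange(n) % 2,
            "batch": np.arange(n) % batch_count,
            "contaminated": [i in set(contaminated) for i in ids],
            "diabetes": [i in set(diabetic) for i in ids],
        },
        index=pd.Index(ids, name="individual_id"),
    )
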