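import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import haplopop as hp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(calls, groups=None, chrom="chr1", pos_start=1, pos_step=1):
    """Small Dataset from a literal call matrix (None -> missing)."""
    calls = np.array([[hp.MISSING if v is None else v for v in row] for row in calls],
                     dtype=np.int8)
    n_ind, n_snp = calls.shape
    if groups is None:
        groups = ["g1"] * n_ind
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(n_snp)],
        "chrom": chrom,
        "pos": np.arange(pos_start, pos_start + pos_step * n_snp, pos_step),
        "ref": "A",
        "alt": "T",
    })
    samples = pd.DataFrame({
        "sample_id": [f"i{i}" for i in range(n_ind)],
        "group": groups,
        "n_calls": 0,
    })
    return hp.Dataset(calls, snps, samples)


@pytest.fixture
def toy_dataset():
    """4 individuals x 6 SNPs with holes, two groups."""
    return make_dataset(
        [[0, 1, 0, 1, None, 0],
         [0, 1, 1, None, 1, 0],
         [1, 0, 0, 1, 1, None],
         [1, None, 1, 0, 0, 1]],
        groups=["a", "a", "b", "b"],
    )


@pytest.fixture
def two_pop_dataset():
    """Two clearly separated simulated populations, no missing data."""
    cfg = hp.SimConfig(n_pops=2, n_snps=5000, pop_F=(0.1, 0.1),
                       sample_sizes=(50, 50), missing_rate=0.0, seed=11)
    ds, truth = hp.build_dataset(cfg)
    return ds, truth
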