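import numpy as np
import pandas as pd
import pytest

import methylpipe as mp
from methylpipe.io import MethylationMatrix


def matrix_from_counts(meth, coverage, chroms, positions, samples) -> MethylationMatrix:
    """Build a MethylationMatrix directly from count arrays (test helper)."""
    meth = np.asarray(meth)
    coverage = np.asarray(coverage)
    idx = [f"{c}:{p}" for c, p in zip(chroms, positions)]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(coverage > 0, meth / np.maximum(coverage, 1), np.nan)
    return MethylationMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=samples),
        coverage=pd.DataFrame(coverage, index=idx, columns=samples),
    )


def matrix_from_beta(beta_2d, chroms, positions, samples, coverage=50) -> MethylationMatrix:
    """Exact-beta matrix with constant coverage (test helper)."""
    beta = np.asarray(beta_2d, dtype=float)
    cov = np.full(beta.shape, coverage, dtype=int)
    cov[np.isnan(beta)] = 0
    idx = [f"{c}:{p}" for c, p in zip(chroms, positions)]
    return MethylationMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=samples),
        coverage=pd.DataFrame(cov, index=idx, columns=samples),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at desk scale (22 LTS vs 14 STS)."""
    cfg = mp.SimulationConfig(n_sites=800, frac_dm=0.05, effect_delta=0.25, seed=11)
    return mp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_groups(small_cohort):
    return small_cohort.samples.set_index("sample_id")["group"]
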