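import numpy as np
import pandas as pd
import pytest

from latentfm.finemap import RegionData
from latentfm.gwas import SumStats


def make_sumstats(z, n=10_000, se=None, bp=None, trait="f", eaf=0.3):
    """Summary-statistics table from z-scores on the standardized scale."""
    z = np.asarray(z, dtype=float)
    p = len(z)
    se = np.full(p, 1 / np.sqrt(n)) if se is None else np.asarray(se, float)
    from scipy.special import ndtr

    tab = pd.DataFrame(
        {
            "SNPID": [f"v{i + 1}" for i in range(p)],
            "CHR": "1",
            "BP": np.arange(p) * 1000 + 1 if bp is None else bp,
            "EA": "A",
            "OA": "G",
            "EAF": eaf,
            "BETA": z * se,
            "SE": se,
            "P": np.clip(2 * ndtr(-np.abs(z)), 1e-300, 1.0),
            "INFO": 1.0,
            "N": n,
        }
    )
    return SumStats(tab, trait)


def make_region(z, ld, n=10_000, se=None, trait="f"):
    return RegionData(make_sumstats(z, n=n, se=se, trait=trait), np.asarray(ld, float), n=n)


def ar1_corr(p, r):
    idx = np.arange(p)
    return r ** np.abs(idx[:, None] - idx[None, :])


@pytest.fixture
def region_factory():
    return make_region


@pytest.fixture
def sumstats_factory():
    return make_sumstats
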