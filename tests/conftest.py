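import numpy as np
import pandas as pd
import pytest

from bpmr.instruments import LDMatrix
from bpmr.sumstats import CANONICAL_COLUMNS


def make_records(rows) -> pd.DataFrame:
    """Build a canonical summary-statistics frame from compact row dicts."""
    defaults = dict(chrom="1", pos=1000, eaf=0.3, n=1000.0)
    full = []
    for i, row in enumerate(rows):
        r = {**defaults, "pos": 1000 + i, **row}
        full.append(r)
    return pd.DataFrame(full, columns=CANONICAL_COLUMNS)


def make_instruments(beta_x, se_x, beta_y, se_y) -> pd.DataFrame:
    """Harmonized-instrument frame from effect arrays."""
    j = len(beta_x)
    return pd.DataFrame({
        "variant_id": [f"rs{i + 1:03d}" for i in range(j)],
        "beta_x": np.asarray(beta_x, float),
        "se_x": np.asarray(se_x, float),
        "beta_y": np.asarray(beta_y, float),
        "se_y": np.asarray(se_y, float),
    })


def random_instruments(rng, j=50, theta=0.05):
    gamma = rng.normal(0.5, 0.15, j) * rng.choice([-1, 1], j)
    se_x = np.full(j, 0.04)
    se_y = rng.uniform(0.01, 0.03, j)
    bx = rng.normal(gamma, se_x)
    by = rng.normal(theta * gamma, se_y)
    return make_instruments(bx, se_x, by, se_y)


def ar1_ld(ids, rho):
    idx = np.arange(len(ids))
    return LDMatrix(ids, rho ** np.abs(idx[:, None] - idx[None, :]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
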