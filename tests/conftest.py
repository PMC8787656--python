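import numpy as np
import pytest

import bsmaskit as bk
from bsmaskit import lpa
from bsmaskit.simulate import ITEM_COLUMNS


@pytest.fixture(scope="session")
def uk_cohort():
    """One UK-like cohort (n=2000) shared by read-only tests."""
    return bk.generate_cohort(bk.uk_like_spec(n=2000, seed=7))


@pytest.fixture(scope="session")
def uk_ratings(uk_cohort):
    return uk_cohort[list(ITEM_COLUMNS)].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def uk_fit3(uk_ratings):
    """A converged 3-class fit on the shared cohort."""
    return lpa.fit_lpa(uk_ratings, 3, n_starts=10, seed=11)


@pytest.fixture(scope="session")
def separated_two_cluster():
    """Continuous two-cluster data: means 1.5 vs 4.5 on every item, sd 0.4."""
    rng = np.random.default_rng(42)
    cls = rng.random(2000) < 0.5
    X = np.where(
        cls[:, None],
        rng.normal(4.5, 0.4, (2000, 6)),
        rng.normal(1.5, 0.4, (2000, 6)),
    )
    return X, cls
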