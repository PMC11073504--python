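import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hallmarktasks.cohort import CohortParams, generate_cohort
from hallmarktasks.io import AbundanceMatrix, GeneSetCollection

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_pair():
    """3 genes x 2 cells, protein == mRNA."""
    data = pd.DataFrame(
        {"c1": [1.0, 2.0, 4.0], "c2": [3.0, 1.0, 5.0]}, index=["gA", "gB", "gC"]
    )
    return (
        AbundanceMatrix("mrna", data.copy()),
        AbundanceMatrix("protein", data.copy()),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortParams(n_cells=8, n_genes=400, n_drugs=12, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_collection(sets: dict, universe=None) -> GeneSetCollection:
    if universe is None:
        seen = {}
        for members in sets.values():
            for m in members:
                seen.setdefault(m)
        universe = list(seen)
    return GeneSetCollection(universe=universe, sets=sets)
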