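import numpy as np
import pandas as pd
import pytest

import lsca


@pytest.fixture(scope="session")
def small_design() -> lsca.SyntheticDesign:
    return lsca.SyntheticDesign(n_genes=600, markers_per_type=30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_design) -> lsca.SyntheticCohort:
    return lsca.simulate_cohort(small_design)


@pytest.fixture(scope="session")
def noiseless_design() -> lsca.SyntheticDesign:
    return lsca.SyntheticDesign(n_genes=600, markers_per_type=30, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_design) -> lsca.SyntheticCohort:
    return lsca.simulate_cohort(noiseless_design)


@pytest.fixture()
def toy_expression() -> lsca.ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["A", "B", "C"], columns=["s1", "s2"],
    )
    return lsca.ExpressionMatrix(values, scale="linear")


def make_fractions(n: int, k: int = 5, alpha: float = 1.0, seed: int = 0):
    """Dirichlet fraction matrix with generic cell-type names c0..c{k-1}."""
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.full(k, alpha), size=n)
    return lsca.FractionMatrix(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(n)],
                     columns=[f"c{j}" for j in range(k)])
    )
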