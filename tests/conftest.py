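import numpy as np
import pytest

from nvucca.prep import build_matrices, invert_scores
from nvucca.simulate import LatentStructureSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the reference study conditions (80 subjects, 7 excluded)."""
    return generate_cohort(LatentStructureSpec(seed=11))


@pytest.fixture(scope="session")
def standard_pair(default_cohort):
    table, _ = default_cohort
    return build_matrices(invert_scores(table))


def random_pair(rng, n, p, q, rho1=0.0):
    """Generic correlated matrix pair for solver tests (not the cohort schema)."""
    z = rng.standard_normal((n, 1))
    X = rho1 * z + np.sqrt(1 - rho1**2) * rng.standard_normal((n, p)) \
        if rho1 else rng.standard_normal((n, p))
    Y = rho1 * z + np.sqrt(1 - rho1**2) * rng.standard_normal((n, q)) \
        if rho1 else rng.standard_normal((n, q))
    return X, Y
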