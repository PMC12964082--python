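import numpy as np
import pytest

from dextral.io import FamilialStudy, load_fixture_familial, load_fixture_twins
from dextral.model import BaseParams

#: the Laland et al. (1995) two-parameter point estimates
LALAND = BaseParams(rho=0.277, alpha=0.138, beta=0.0)


@pytest.fixture(scope="session")
def laland_params():
    return LALAND


@pytest.fixture(scope="session")
def familial_fixture():
    """Bundled synthetic 17-study familial dataset (reported incidences)."""
    return load_fixture_familial(incidence_mode="reported")


@pytest.fixture(scope="session")
def twin_fixture():
    """Bundled pooled MZ/DZ twin dataset."""
    return load_fixture_twins()


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


def make_study(counts, pairs=None, m_p=None, study_id="test"):
    return FamilialStudy(
        study_id=study_id,
        offspring_counts=np.asarray(counts),
        parental_pair_counts=None if pairs is None else np.asarray(pairs),
        reported_parent_incidence=m_p,
    )


def random_valid_params(rng, allow_beta=False):
    rho = rng.uniform(0.0, 0.49)
    alpha = rng.uniform(0.0, 0.5 - rho)
    beta = rng.uniform(-0.2, min(0.2, 0.5 - rho)) if allow_beta else 0.0
    return BaseParams(rho=rho, alpha=alpha, beta=beta)
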