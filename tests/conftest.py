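import numpy as np
import pytest

from tiliapop.genotype_core import MISSING, GenotypeDataset
from tiliapop.synthetic_data import FixtureConfig, make_study_fixture


@pytest.fixture(scope="session")
def study_fixture() -> GenotypeDataset:
    """The study-shaped synthetic dataset: 11 populations, N=242, 15 loci."""
    return make_study_fixture(FixtureConfig(seed=1))


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """Two populations x three individuals, two loci, one missing genotype."""
    calls = np.array(
        [
            [[180, 182], [200, 200]],
            [[180, 180], [200, 202]],
            [[182, 182], [MISSING, MISSING]],
            [[184, 186], [204, 204]],
            [[184, 184], [202, 204]],
            [[186, 186], [202, 202]],
        ]
    )
    return GenotypeDataset(
        individuals=[f"i{k}" for k in range(6)],
        populations=["A"] * 3 + ["B"] * 3,
        loci=["L1", "L2"],
        calls=calls,
    )
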