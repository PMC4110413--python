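import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_matrix():
    """Six homozygous lines at four loci, no missing data."""
    from ssrpop import GenotypeMatrix

    calls = np.array(
        [
            [100, 200, 300, 400],
            [100, 200, 300, 402],
            [102, 202, 300, 400],
            [102, 202, 302, 404],
            [104, 200, 300, 400],
            [104, 204, 302, 406],
        ]
    )
    return GenotypeMatrix(
        [f"acc{i}" for i in range(6)], [f"l{j}" for j in range(4)], calls
    )
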