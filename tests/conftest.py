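import numpy as np
import pytest
from hypothesis import settings

from svcrkit.synthetic import CohortSpec, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 9-sample cohort with two trios, small enough for exhaustive oracles."""
    spec = CohortSpec(
        n_samples=9,
        n_trios=2,
        contigs=(("chr1", 3000), ("chr2", 2000)),
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
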