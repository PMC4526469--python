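import numpy as np
import pytest

from sealniche.study import run_chronology
from sealniche.synthetic import SyntheticTruth, generate_population


@pytest.fixture(scope="session")
def truth1():
    return SyntheticTruth(rng_seed=1)


@pytest.fixture(scope="session")
def pop1(truth1):
    """One full synthetic population (6 males + 6 females), seed 1."""
    return generate_population(truth1)


@pytest.fixture(scope="session")
def chron1(pop1):
    """Fitted, synchronized, windowed chronologies of the seed-1 population."""
    results, summary, window = run_chronology(pop1.whiskers, seed=1)
    return {"results": results, "summary": summary, "window": window}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
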