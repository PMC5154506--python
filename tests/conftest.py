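import pandas as pd
import pytest

from avcausal import ObserverConfig, simulate
from avcausal.core import CausalPosterior, GaussianEstimate, UnimodalProfile


@pytest.fixture
def profile_pair():
    """Auditory N(5, 4) and visual N(3, 1) — fused mean 3.4, variance 0.8."""
    return (
        UnimodalProfile("auditory", 5.0, 5.0, 4.0),
        UnimodalProfile("visual", 3.0, 3.0, 1.0),
    )


@pytest.fixture
def estimates():
    """Common-cause and separate-cause Gaussian estimates used across tests."""
    return GaussianEstimate(3.4, 0.8), GaussianEstimate(5.0, 4.0)


@pytest.fixture
def posterior_03():
    return CausalPosterior(p_common=0.3)


@pytest.fixture(scope="session")
def study_data():
    """One simulated run of the full study design (6 subjects, 6 reps)."""
    return simulate(ObserverConfig(seed=11))


def make_response_rows(rows):
    """Build a response table from (subject, cond, v, a, rv, ra, rep) tuples."""
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "vis_dist", "aud_dist", "resp_vis", "resp_aud", "rep"],
    )
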