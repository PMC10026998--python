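import numpy as np
import pytest

from slodrlab import (
    CorrelationSpec,
    McfaSettings,
    TrueSlodrParams,
    pc1_scores,
    sample_mvn,
    simulate_true_slodr,
)


@pytest.fixture(scope="session")
def small_mvn_cohort():
    return sample_mvn(CorrelationSpec.case_selection_default(), 800, seed=42)


@pytest.fixture(scope="session")
def small_slodr_cohort():
    return simulate_true_slodr(TrueSlodrParams(), 800, seed=43)


@pytest.fixture(scope="session")
def small_slodr_moderator(small_slodr_cohort):
    return pc1_scores(small_slodr_cohort)


@pytest.fixture(scope="session")
def fast_mcfa_settings():
    """Two jittered restarts: enough for these well-conditioned problems,
    keeps the grids quick."""
    return McfaSettings(n_restarts=2)
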