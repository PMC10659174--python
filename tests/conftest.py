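import pytest

import atpflow as af


@pytest.fixture
def normal_pp() -> af.PopulationParams:
    """Calibrated normal plasma-cell phenotype (printed growth rate)."""
    return af.PopulationParams(r=1.39e-2, tau=72.0, K=4.05e21, eta=0.4)


@pytest.fixture
def calibrated_cp() -> af.CompetitionParams:
    """Calibrated competition setting at the fastest malignant phenotype."""
    return af.CompetitionParams(
        r1=1.39e-2, r2=1.53e-2, tau1=72.0, tau2=72.0, K=4.05e21, c=0.0
    )


@pytest.fixture(scope="session")
def growth_sweep():
    """Takeover runs across the malignant growth-rate grid (shared: slow)."""
    return af.run_takeover_growth_sweep()


@pytest.fixture(scope="session")
def interaction_sweep():
    """Takeover runs across the interaction-scale grid (shared: slow)."""
    return af.run_takeover_interaction_sweep()
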