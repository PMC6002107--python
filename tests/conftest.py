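import pytest

import respsim as r


@pytest.fixture(scope="session")
def params_high():
    return r.RespiratoryParameters(d_w=0.48)


@pytest.fixture(scope="session")
def params_low():
    return r.RespiratoryParameters(d_w=2.4)


@pytest.fixture(scope="session")
def rec():
    return r.RecruitmentState()


def _steady(condition: str, braking: bool):
    cfg = r.ScenarioConfig(cw_condition=condition, braking=braking)
    return r.steady_state(cfg.parameters(), cfg.recruitment(), cfg.amplitude,
                          f=1.0,
                          expiratory_multiplier=cfg.expiratory_multiplier)


@pytest.fixture(scope="session")
def steady_states():
    """Converged (trace, summary) for the four published breathing
    conditions, keyed by (cw_condition, braking)."""
    return {(cw, br): _steady(cw, br)
            for cw in ("high", "low") for br in (False, True)}


@pytest.fixture(scope="session")
def ttf_high_none():
    """Time to failure of the high-compliance, no-intervention run."""
    return r.run_simulation(r.SCENARIO_REGISTRY["S3"])


@pytest.fixture(scope="session")
def ttf_low_none():
    """Time to failure of the low-compliance, no-intervention run."""
    return r.run_simulation(r.SCENARIO_REGISTRY["S1"])
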