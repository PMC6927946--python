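import pytest

from gonogo.config import AnimalEntry, RunConfig
from gonogo.virtual_rig import AgentParams, simulate_cohort


@pytest.fixture(scope="session")
def perfect_params() -> AgentParams:
    """An agent that never fails a gate and always responds correctly."""
    return AgentParams(
        h0=1.0, h_inf=1.0, f0=0.0, f_inf=0.0,
        p_rfid_fail=0.0, p_presample_fail=0.0, pretrain_lick_prob=1.0,
    )


@pytest.fixture(scope="session")
def perfect_run(perfect_params):
    """Flawless single animal simulated through pre-training and beyond."""
    cfg = RunConfig(cohort=[AnimalEntry("m1")], agents=perfect_params)
    return simulate_cohort(cfg, 96.0, seed=3)


@pytest.fixture(scope="session")
def learning_run():
    """One learning agent, discrimination only, ~2500 completed trials."""
    cfg = RunConfig(
        cohort=[AnimalEntry("m1")],
        agents=AgentParams(tau=120.0, p_rfid_fail=0.0, p_presample_fail=0.0),
    )
    return simulate_cohort(cfg, 24.0 * 10, seed=11, skip_pretraining=True)


@pytest.fixture(scope="session")
def cohort_run():
    """Five stochastic agents sharing one port for three simulated days."""
    cfg = RunConfig(cohort=[AnimalEntry(f"m{i}", group="g1") for i in range(5)])
    return simulate_cohort(cfg, 72.0, seed=7)
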