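import numpy as np
import pandas as pd
import pytest

import valsight as vs


@pytest.fixture(scope="session")
def default_config():
    return vs.TaskConfig()


@pytest.fixture(scope="session")
def small_config():
    return vs.TaskConfig(n_learning_trials=60, n_transfer_trials=60)


@pytest.fixture(scope="session")
def agent():
    return vs.AgentParams(alpha_gain=0.3, alpha_loss=0.15, beta=8.0)


@pytest.fixture(scope="session")
def learning_records(small_config, agent):
    sched = vs.build_learning_schedule(small_config, seed=11)
    rec, tr = vs.simulate_agent(agent, sched, small_config, seed=12)
    return rec, tr


@pytest.fixture(scope="session")
def session_records(small_config, agent):
    """Learning + transfer records/qtrace for one subject."""
    return vs.simulate_subject(agent, small_config, seed=21)


@pytest.fixture(scope="session")
def separable_betas(small_config, agent):
    """Noise-free, label-coupled transfer beta matrix."""
    rec, tr = vs.simulate_subject(agent, small_config, seed=31)
    cfg = vs.RoiSignalConfig(beta_noise_sd=0.0, beta_couple_dvalue=False)
    return vs.synthesize_trial_betas(rec, tr, cfg, seed=32)


@pytest.fixture(scope="session")
def planted_cohort_betas(default_config):
    """Moderate-noise cohort beta tables with value-coupled signal."""
    hyper = vs.GroupHyperParams()
    cfg = vs.TaskConfig(n_learning_trials=150, n_transfer_trials=120)
    records, qtraces, _ = vs.simulate_cohort(hyper, cfg, 12, seed=77)
    roi_cfg = vs.RoiSignalConfig(beta_noise_sd=0.6)
    betas = vs.synthesize_trial_betas(records, qtraces, roi_cfg, seed=78)
    return [g for _, g in betas.groupby("subject_id", sort=True)]
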