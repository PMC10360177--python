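"""Shared fixtures: one default config and a few session-scoped simulations
that several test modules analyze (simulations are deterministic, so sharing
them is safe and keeps the suite fast)."""

import pytest

from pacesim import RunConfig, simulate_trial
from pacesim.runner import run_cohort


@pytest.fixture()
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def cfg_session():
    return RunConfig()


@pytest.fixture(scope="session")
def rec_combined_500(cfg_session):
    """500-cycle combined-mode closed-loop trial, default plant, fixed seed."""
    return simulate_trial(cfg_session, mode="combined", sigh=False,
                          duration_s=500 * 1.53, seed=1)


@pytest.fixture(scope="session")
def rec_dia_550(cfg_session):
    return simulate_trial(cfg_session, mode="dia_only", sigh=False,
                          duration_s=550 * 1.53, seed=1)


@pytest.fixture(scope="session")
def rec_combined_550(cfg_session):
    return simulate_trial(cfg_session, mode="combined", sigh=False,
                          duration_s=550 * 1.53, seed=1)


@pytest.fixture(scope="session")
def rec_sigh_combined(cfg_session):
    """95-cycle combined trial with sighs every 30 cycles (3 sighs)."""
    return simulate_trial(cfg_session, mode="combined", sigh=True,
                          duration_s=95 * 1.53, seed=3)


@pytest.fixture(scope="session")
def rec_sigh_dia(cfg_session):
    return simulate_trial(cfg_session, mode="dia_only", sigh=True,
                          duration_s=95 * 1.53, seed=3)


@pytest.fixture(scope="session")
def cohort6(cfg_session):
    """Six jittered subjects, matched 550-cycle dia-only and combined trials."""
    return run_cohort(cfg_session, n_subjects=6, seed=1, n_cycles=550)
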