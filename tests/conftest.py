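import numpy as np
import pytest

from moodrisk import (
    ChoiceModel,
    ChoiceParams,
    MoodParams,
    QuizDesign,
    simulate_subject,
)


@pytest.fixture(scope="session")
def design():
    return QuizDesign()


@pytest.fixture(scope="session")
def sim_subject():
    """One simulated subject with known generating parameters (3 sessions)."""
    mp = MoodParams(w0=0.0, wf=0.1, wt=0.0, gamma=0.7, delta=0.3, R=1.0)
    cp = ChoiceParams(k0=0.0, kg=1.0, kl=1.0, sigma=0.06, kt=0.0)
    trials, truth = simulate_subject(
        QuizDesign(), mp, cp, rating_noise_sd=0.1, n_sessions=3, seed=7
    )
    return trials, truth


@pytest.fixture(scope="session")
def choice_fit(sim_subject):
    trials, _ = sim_subject
    return ChoiceModel.from_trials(trials).fit()
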