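import numpy as np
import pytest

from revlearn.models import ModelSpec, Params, simulate_subject
from revlearn.stats import session_metrics
from revlearn.task import SessionData, TaskConfig, TrialRecord

DU2RA = ModelSpec.from_code("DU-2rho-1alpha")

# printed population means of the winning model's parameters
MID_PARAMS = dict(alpha=0.625, rho_win=2.49, rho_loss=-0.715)
WAVE1_PARAMS = dict(alpha=0.61, rho_win=2.36, rho_loss=-0.77)


@pytest.fixture(scope="session")
def du_spec() -> ModelSpec:
    return DU2RA


@pytest.fixture(scope="session")
def mid_params() -> Params:
    return Params.from_natural(DU2RA, **MID_PARAMS)


@pytest.fixture(scope="session")
def wave1_params() -> Params:
    return Params.from_natural(DU2RA, **WAVE1_PARAMS)


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


def make_session(choices, feedback_signs, good=0, subject="toy", wave=1,
                 config=None) -> SessionData:
    """Hand-build a session with a fixed good stimulus and given feedback."""
    config = config or TaskConfig()
    trials = []
    for i, (c, f) in enumerate(zip(choices, feedback_signs)):
        missing = c is None
        trials.append(
            TrialRecord(
                trial_index=i,
                choice=c,
                correct=None if missing else (c == good),
                feedback_sign=None if missing else f,
                feedback_value=None if missing else (
                    config.win_amount if f > 0 else config.loss_amount
                ),
                reversal_after=False,
                good_stimulus=good,
            )
        )
    return SessionData(subject=subject, wave=wave, config=config, trials=trials)


def simulate_agents(params: Params, n: int, seed: int, config=None):
    """Simulate n sessions and return their metrics."""
    config = config or TaskConfig()
    out = []
    for child in np.random.SeedSequence(seed).spawn(n):
        out.append(session_metrics(simulate_subject(params, config=config,
                                                    seed=child)))
    return out


@pytest.fixture(scope="session")
def mid_cohort_metrics(mid_params):
    """1000 simulated agents at mid-study mean parameters (shared by the
    stay/accuracy/reward acceptance checks)."""
    return simulate_agents(mid_params, n=1000, seed=20_001)
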