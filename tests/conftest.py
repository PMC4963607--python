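import numpy as np
import pytest

from ictrain import engine
from ictrain.agents import Agent


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def game_config():
    return engine.GameConfig()


@pytest.fixture
def learner_log():
    """One full 140-game course played by the default learning agent."""
    return engine.run_course(
        Agent.preset("learner"),
        engine.GameConfig(),
        140,
        np.random.default_rng(42),
        participant_id="P001",
    )


def make_game_record(
    game_index=1,
    level=1,
    mean_rt_ms=400.0,
    n_correct_go=22,
    n_correct_nogo=5,
    n_errors=2,
    n_omissions=1,
):
    return engine.GameRecord(
        game_index=game_index,
        level=level,
        mean_rt_ms=mean_rt_ms,
        n_correct_go=n_correct_go,
        n_correct_nogo=n_correct_nogo,
        n_errors=n_errors,
        n_omissions=n_omissions,
    )
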