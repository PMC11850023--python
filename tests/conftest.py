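from hypothesis import HealthCheck, settings
import pytest

from urnlearn import HypothesisSpace, Jar, exp1_space, plain_space

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ball_space() -> HypothesisSpace:
    """Experiment 1 jars: 5:1 plus one distractor ball unique to each jar."""
    return exp1_space()


@pytest.fixture
def toy_space() -> HypothesisSpace:
    """Two-colour 5:1 toy jars (frog/fish)."""
    return plain_space()


@pytest.fixture
def tie_space() -> HypothesisSpace:
    """A space with a colour equally likely under both jars (forces a tie)."""
    return HypothesisSpace(
        [Jar("left", {"blue": 2, "pink": 2}), Jar("right", {"blue": 2, "teal": 2})]
    )
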