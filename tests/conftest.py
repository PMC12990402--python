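import pytest

from cldkit import (
    CausalLoopDiagram,
    Connection,
    Variable,
    published_fixtures,
)


@pytest.fixture(scope="session")
def triad():
    """Fully bidirectional sleep / depressive-symptoms / smoking triad."""
    return published_fixtures()["smoking_triad"]


@pytest.fixture(scope="session")
def wb_loop():
    """Six-variable cross-scale loop through well-being."""
    return published_fixtures()["well_being_loop"]


@pytest.fixture
def two_cycle():
    """Minimal diagram: a <-> b."""
    return CausalLoopDiagram(
        [Variable("a", "A", "biological"), Variable("b", "B", "biological")],
        [Connection("a", "b", "positive"), Connection("b", "a", "positive")],
        name="two-cycle",
    )


@pytest.fixture
def star():
    """a -> b, a -> c (acyclic, a exogenous)."""
    return CausalLoopDiagram(
        [
            Variable("a", "A", "social"),
            Variable("b", "B", "social"),
            Variable("c", "C", "psychological"),
        ],
        [Connection("a", "b", "positive"), Connection("a", "c", "negative")],
        name="star",
    )
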