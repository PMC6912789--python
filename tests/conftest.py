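import pytest

from agonet import (
    GeneratorConfig,
    InteractionEvent,
    PenRoster,
    generate_study,
)


def _ev(pen, t, init, recv, winner=None, loser=None):
    decisive = winner is not None
    return InteractionEvent(pen, t, init, recv, winner, loser, decisive)


@pytest.fixture(scope="session")
def example_pen():
    """Six-pig worked example: pig 4 initiates four fights but wins only two
    (against pigs 2 and 3); pig 3 is attacked by pigs 4 and 6 and loses both;
    pig 1 never interacts."""
    roster = PenRoster("PEX", ("1", "2", "3", "4", "5", "6"))
    events = [
        _ev("PEX", 0.2, "4", "2", "4", "2"),
        _ev("PEX", 0.4, "4", "3", "4", "3"),
        _ev("PEX", 0.6, "4", "5", "5", "4"),
        _ev("PEX", 0.8, "4", "6", "6", "4"),
        _ev("PEX", 1.5, "6", "3", "6", "3"),
    ]
    return roster, events


@pytest.fixture(scope="session")
def small_study():
    """Five-pen piglet simulation at the default study conditions."""
    return generate_study(GeneratorConfig(n_pens=5, seed=42))
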