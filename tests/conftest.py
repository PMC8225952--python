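import pytest

from cetasong.annotations import tokenize_label_string
from cetasong.synth import SessionScenario


def tok(s: str):
    return tuple(tokenize_label_string(s))


@pytest.fixture(scope="session")
def small_scenario() -> SessionScenario:
    """Four-stimulus noiseless scenario at a low rate, cheap to render."""
    return SessionScenario(
        stimulus_schedule=(("P1", 1.0), ("P1", 12.0), ("P1", 23.0), ("P1", 34.0)),
        response_grammar={"P1": [(tok("C2C2D"), 1.0)]},
        noise_rates=(0.0, 0.0, 0.0),
        inter_unit_silence=(0.1, 0.3),
        sample_rate=8000,
        seed=11,
    )
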