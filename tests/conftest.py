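import numpy as np
import pytest

from smartmar import fixtures as fx

NYHA_TRANSITIONS = [
    ("physical functioning", "NYHA IV", "NYHA III"),
    ("physical functioning", "NYHA IV", "NYHA II"),
    ("physical functioning", "NYHA IV", "NYHA I"),
    ("physical functioning", "NYHA III", "NYHA II"),
    ("physical functioning", "NYHA III", "NYHA I"),
    ("physical functioning", "NYHA II", "NYHA I"),
]

DEATH = "30-day death"
BLEED = "severe bleeding"


@pytest.fixture(scope="session")
def hf_model():
    """Heart-failure study model, censored at 20%."""
    return fx.heart_failure_model()


@pytest.fixture(scope="session")
def death_curve(hf_model):
    return hf_model.risk(DEATH)


@pytest.fixture(scope="session")
def bleeding_curve(hf_model):
    return hf_model.risk(BLEED)


@pytest.fixture(scope="session")
def nyha_transitions():
    return list(NYHA_TRANSITIONS)
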