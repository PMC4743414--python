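import numpy as np
import pytest

from enhanceodimer.motif_model import PWM
from enhanceodimer.synthetic_data import random_pwm


@pytest.fixture
def uniform_pwm() -> PWM:
    """A PWM whose every column equals the uniform background (score 0 everywhere)."""
    return PWM(id="UNIF", counts=np.full((4, 4), 25.0), pseudocount_fraction=0.0)


@pytest.fixture
def pwm_factory():
    """Seeded random-PWM factory for oracle and property tests."""

    def make(width: int, seed: int, motif_id: str | None = None) -> PWM:
        return random_pwm(motif_id or f"R{width}_{seed}", width, seed=seed)

    return make
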