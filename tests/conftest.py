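import numpy as np
import pytest

from cluniosim import ModelParams


@pytest.fixture
def flat_params() -> ModelParams:
    """Single niche, ecological pools, all females mate, flat fecundity."""
    return ModelParams()


@pytest.fixture
def tradeoff_params() -> ModelParams:
    """Clear growth-survival tradeoff (fecundity rising with pending weeks)."""
    return ModelParams(fecundity=(60.0, 90.0, 120.0, 150.0))


@pytest.fixture
def lossless_params() -> ModelParams:
    """No mortality, no maturation below age 11: pure aging for conservation
    checks."""
    return ModelParams(
        s_max=1.0,
        alpha=0.0,
        maturation=(0.0, 0.0, 0.0, 0.0, 0.0, 1.0),
    )


@pytest.fixture
def equal_thirds() -> dict:
    return {"FF": 1 / 3, "M1M1": 1 / 3, "M2M2": 1 / 3}


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
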