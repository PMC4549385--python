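import numpy as np
import pytest

from gmvrec.recovery import DEFAULT_VISIT_DAYS
from gmvrec.synthcohort import DEFAULT_MODEL_PARAMS, evaluate_model


@pytest.fixture
def visit_days():
    return np.asarray(DEFAULT_VISIT_DAYS, dtype=float)


@pytest.fixture
def subgroup_model():
    """Noise-free subgroup trajectory evaluator: (label, t) -> z."""

    def _eval(label, t):
        return evaluate_model(DEFAULT_MODEL_PARAMS[label], np.asarray(t, float), label)

    return _eval
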