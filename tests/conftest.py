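import numpy as np
import pytest

from gpdgrowth import GPDParams


@pytest.fixture
def case_params():
    """One representative parameter set per qualitative case."""
    return {
        "i": GPDParams(1.0, 1.0, 1.0, 3.0),
        "ii": GPDParams(0.1, 1.0, -0.2, 3.0),     # 1/|a| = 5 (odd)
        "iii": GPDParams(1.0, 1.0, -0.5, 3.0),    # 1/|a| = 2 (even)
        "iv": GPDParams(1.0, 1.0, -0.3, 3.0),     # 1/|a| non-integer
    }


@pytest.fixture
def sigmoidal_params():
    """A case-(i) set with A*b > a+1 so all tangent features exist."""
    return GPDParams(0.1, 3.0, 2.0, 2.0)


def grid_for(p: GPDParams, n: int = 200, margin: float = 0.98) -> np.ndarray:
    """Dense time grid inside the domain of a parameter set."""
    if p.a > 0:
        return np.linspace(0.0, 10.0, n)
    return np.linspace(0.0, margin * p.b / abs(p.a), n)
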