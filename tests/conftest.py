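import numpy as np
import pytest

from trtcart.dynamics import ModelParameters
from trtcart.regimens import RegimenSpec, run_regimen, sweep_second_therapy


@pytest.fixture(scope="session")
def params():
    """Reference parameter set (experimentally derived defaults)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def mono_outcomes(params):
    """Endpoints of the day-7 monotherapy regimens, simulated once."""
    out = {}
    for kind in ("trt_only", "cart_only"):
        out[kind] = run_regimen(RegimenSpec(kind=kind), params)[1]
    return out


@pytest.fixture(scope="session")
def combo_outcomes_7d(params):
    """Endpoints of both combination orderings at the 7-day interval."""
    out = {}
    for kind in ("cart_then_trt", "trt_then_cart"):
        out[kind] = run_regimen(RegimenSpec(kind=kind, interval_days=7.0),
                                params)[1]
    return out


@pytest.fixture(scope="session")
def sweeps(params):
    """Second-therapy sweeps (days 14-80, 1-day step) for both orderings."""
    return {kind: sweep_second_therapy(kind, params)
            for kind in ("cart_then_trt", "trt_then_cart")}


@pytest.fixture(scope="session")
def sweep_grid():
    return np.arange(14.0, 81.0, 1.0)
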