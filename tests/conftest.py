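import numpy as np
import pytest

from btkpkpd import DosingRegimen, PKParameters, TurnoverParameters


@pytest.fixture
def one_cpt_params():
    """Collapsed one-compartment, first-order-absorption parameter set."""
    return PKParameters(CL=5.0, Vc=20.0, Q=0.0, Vp=0.0, ktr=1.2, F=0.8, n_transit=0)


@pytest.fixture
def two_cpt_params():
    return PKParameters(CL=5.0, Vc=20.0, Q=10.0, Vp=50.0, ktr=2.0, F=1.0, n_transit=3)


@pytest.fixture
def turnover():
    return TurnoverParameters(ksyn=0.02, kdeg=0.01, kbind=0.03)


@pytest.fixture
def single_dose():
    return DosingRegimen(dose_amount=100.0)


def aligned_grid(t_end: float, step: float = 0.1) -> np.ndarray:
    """Uniform grid whose step divides typical dosing intervals, so that
    time-shifted superposition lands exactly on grid nodes."""
    return np.round(np.arange(0.0, t_end + step / 2, step), 10)
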