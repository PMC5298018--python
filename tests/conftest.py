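import warnings

import numpy as np
import pytest

from dantespace import flipangle_design as fa


@pytest.fixture(scope="session")
def timing():
    return fa.SequenceTiming.protocol_7t()


@pytest.fixture(scope="session")
def target(timing):
    return fa.prescribed_evolution(timing)


@pytest.fixture(scope="session")
def optimized_scheme(timing, target):
    """Flip-angle train designed for vessel wall relaxation times at 7T."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fa.design_flip_angles(target, fa.VESSEL_WALL_7T, timing)


@pytest.fixture(scope="session")
def default_scheme(timing, target):
    """Reconstruction of the vendor train (designed for T1/T2 = 940/100 ms)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fa.design_flip_angles(target, fa.VENDOR_DEFAULT, timing)


@pytest.fixture(scope="session")
def cpmg_scheme(timing):
    return fa.FlipAngleScheme(
        refocusing_deg=np.full(timing.n_echoes, 180.0), design_tissue=fa.VESSEL_WALL_7T
    )
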