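import numpy as np
import pytest

import capkinetics as ck
from capkinetics.synthetic import GroundTruthSeries, OpticsConfig


@pytest.fixture
def optics():
    """Default optics with a fixed seed for reproducible rendering."""
    return OpticsConfig(seed=11)


@pytest.fixture
def constant_series():
    """Factory for a steady-state capillary series (constant v, LD, SO2)."""

    def make(v=300.0, ld=50.0, so2=70.0, T=5):
        t = np.arange(1, T + 1, dtype=float)
        vel = np.full(T, float(v))
        ldv = np.full(T, float(ld))
        so = np.full(T, float(so2))
        return GroundTruthSeries(
            0, t, vel, ldv, so,
            ck.derive_hematocrit(ldv),
            ck.derive_supply_rate(vel, ldv),
            kinetics={})

    return make
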