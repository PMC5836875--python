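import numpy as np
import pytest

from viscopalp import LoadProtocol, PronyMaterial


@pytest.fixture
def healthy():
    """Baseline non-cancerous phase: 17 kPa, D=0.5, tau=1 s."""
    return PronyMaterial(E0=17e3, terms=((0.5, 1.0),), name="healthy")


@pytest.fixture
def cancerous():
    """Stiffness ratio 1:2, relaxation-time ratio 1:10 relative to healthy."""
    return PronyMaterial(E0=34e3, terms=((0.5, 10.0),), name="cancerous")


@pytest.fixture
def creep_protocol():
    return LoadProtocol(mode="creep", magnitude=1.0, hold_time=5.0, dt=0.05)


@pytest.fixture
def relaxation_step_protocol():
    """Ideal step relaxation: 1 mm platen displacement, 5 s hold."""
    return LoadProtocol(mode="relaxation", magnitude=1e-3, hold_time=5.0,
                        ramp_time=0.0, dt=0.05)


@pytest.fixture
def relaxation_ramp_protocol():
    """Ramped relaxation: 1 s linear ramp then 5 s hold."""
    return LoadProtocol(mode="relaxation", magnitude=1e-3, hold_time=5.0,
                        ramp_time=1.0, dt=0.05)


def prony_modulus_oracle(E0, terms, t):
    """Independent scalar evaluation of the Prony relaxation modulus."""
    import math

    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(E0))
    for D, tau in terms:
        out = out - E0 * D * (1.0 - np.exp(-t / tau))
    return out
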