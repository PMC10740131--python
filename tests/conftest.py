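import numpy as np
import pytest

from quenchbind import QuenchingSeries

#: Worked-example constants: Ksv (M^-1) by temperature (K), lifetime, and
#: Van't Hoff enthalpy/entropy of the bundled example dataset.
KSV_BY_TEMPERATURE = {293.0: 750.0, 303.0: 1120.0, 310.0: 1460.0}
TAU0_S = 1.0e-8
DELTA_H_KJ = -164.076
DELTA_S_KJ = -0.501
TEMPERATURES_K = (293.0, 303.0, 310.0)

#: Working quencher concentrations (M), zero excluded.
CONCENTRATIONS_M = (0.760e-4, 1.520e-4, 2.282e-4, 3.041e-4, 3.802e-4)


def make_sv_series(ksv, temperature=293.0, f0=1000.0, conc=CONCENTRATIONS_M):
    """Noiseless titration obeying F0/F = 1 + Ksv [Q] exactly."""
    conc = np.asarray(conc)
    return QuenchingSeries(
        temperature=temperature,
        concentrations=conc,
        f0=f0,
        f=f0 / (1.0 + ksv * conc),
    )


@pytest.fixture
def sv_series():
    return make_sv_series(1000.0)
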