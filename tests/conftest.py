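import numpy as np
import pytest

import richfit as rf


@pytest.fixture
def gl_series():
    """Factory: noiseless Richards-curve titration series."""

    def make(
        s_floor=0.0,
        s_span=1000.0,
        rate=1.2,
        log_infl=np.log(5e-9),
        nu=0.5,
        n=12,
        decades=3.0,
    ):
        p = rf.GLParams(s_floor, s_span, rate, log_infl, nu)
        conc = np.logspace(
            (log_infl - decades * np.log(10)) / np.log(10),
            (log_infl + decades * np.log(10)) / np.log(10),
            n,
        )
        return rf.TitrationSeries(conc, rf.gl_value(np.log(conc), p)), p

    return make


@pytest.fixture
def fourpl_series():
    """Noiseless symmetric (4PL) titration series with its true parameters."""
    p = rf.FourPLParams(0.0, 800.0, 1.3, np.log(2e-8))
    conc = np.logspace(-10.7, -4.7, 12)
    return rf.TitrationSeries(conc, rf.fourpl_value(np.log(conc), p)), p


@pytest.fixture
def monoclonal_series():
    """Noiseless single-clone Langmuir titration (antibody-dilute)."""
    kd = 1e-8
    mix = rf.ClonalMixture([rf.Clone(kd, 1e-10)])
    assay = rf.AssayConfig(
        conc_grid=rf.log_conc_grid(kd, 3, 12), signal_per_bound=1e12, background=0.0
    )
    return rf.simulate_titration(mix, assay), kd
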