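import numpy as np
import pytest

from ionspec.dielectric import DielectricSpectrum, RelaxationFit, eval_permittivity


@pytest.fixture
def freq_grid():
    """Default measurement grid: 101 log-spaced points, 0.25-125 GHz."""
    return np.geomspace(0.25, 125.0, 101)


@pytest.fixture
def peptide_water_fit():
    """Two-mode model of a 0.25 M dipeptide solution (peptide + water)."""
    return RelaxationFit(S_pep=6.9, tau_pep=160.0, S_wat=71.5, tau_wat=8.3,
                         alpha=0.02, eps_inf=3.5, kappa=0.0)


@pytest.fixture
def peptide_water_spectrum(freq_grid, peptide_water_fit):
    er, ei = eval_permittivity(peptide_water_fit, freq_grid)
    return DielectricSpectrum(freq=freq_grid, eps_real=er, eps_imag=ei,
                              meta={"peptide_conc_M": 0.25})
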