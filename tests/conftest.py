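import numpy as np
import pytest

from cmpreg import thailand_fatality_table
from cmpreg.design import DesignSet
from cmpreg.models import fit_cmp, fit_poisson, fit_zicmp, fit_zip


@pytest.fixture(scope="session")
def freq():
    """The packaged deaths-per-accident frequency table (n = 20,229)."""
    return thailand_fatality_table()


@pytest.fixture(scope="session")
def freq_design(freq):
    return DesignSet.from_frequency(freq)


@pytest.fixture(scope="session")
def fixture_fits(freq_design):
    """All four intercept-only models fitted to the packaged table."""
    return {
        "poisson": fit_poisson(freq_design),
        "cmp": fit_cmp(freq_design),
        "zip": fit_zip(freq_design),
        "zicmp": fit_zicmp(freq_design),
    }


def brute_force_log_z(lam: float, nu: float, j_max: int = 300) -> float:
    """Independent oracle: direct summation of lam**j / (j!)**nu."""
    import math

    total = 0.0
    for j in range(j_max):
        total += math.exp(j * math.log(lam) - nu * math.lgamma(j + 1))
    return math.log(total)


def brute_force_moments(lam: float, nu: float, j_max: int = 300):
    """Independent oracle for the exact CMP mean and variance."""
    import math

    z = math.exp(brute_force_log_z(lam, nu, j_max))
    m1 = sum(
        j * math.exp(j * math.log(lam) - nu * math.lgamma(j + 1)) for j in range(j_max)
    ) / z
    m2 = sum(
        j * j * math.exp(j * math.log(lam) - nu * math.lgamma(j + 1))
        for j in range(j_max)
    ) / z
    return m1, m2 - m1 * m1
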