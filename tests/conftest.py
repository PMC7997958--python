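import numpy as np
import pytest

from pvalmeta.cli_io import bundled_bmi_loci

#: Published two-sided combined p-values (minimum-marginal order-statistic
#: method, directional wrapper) for the bundled BMI loci whose combined
#: value is representable in double precision.
BMI_ORDMETA_PRINTED = {
    "rs7903146": 1.82e-10,
    "rs489693": 7.34e-08,
    "rs2206277": 1.19e-06,
    "rs12243326": 2.03e-09,
    "rs987237": 2.02e-07,
}


@pytest.fixture(scope="session")
def bmi_table():
    return bundled_bmi_loci()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def round_sig(x: float, digits: int = 3) -> float:
    """Round to a number of significant digits (printed-precision compare)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    exp = floor(log10(abs(x)))
    return round(x, -exp + digits - 1)
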