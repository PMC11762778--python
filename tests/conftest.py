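import numpy as np
import pytest

from telosen import (
    InitialDistribution,
    LawParams,
    RngHub,
    SyntheticBankSpec,
    synthetic_bank,
)


@pytest.fixture
def params():
    return LawParams()


@pytest.fixture
def dist():
    return InitialDistribution()


@pytest.fixture(scope="session")
def bank():
    return synthetic_bank(RngHub(1234).misc)


@pytest.fixture
def hub():
    return RngHub(99)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def immortal_params():
    """No arrests, no death: cells divide forever."""
    return LawParams(
        b_nta=0.0,
        b_sen_A=0.0,
        b_sen_B=0.0,
        l_min_A=0.0,
        l_min_B=0.0,
        p_accident=0.0,
        h=0,
    )


@pytest.fixture(scope="session")
def constant_bank():
    """Every cycle lasts exactly 90 min (arrest cycles 240 min)."""
    from telosen.cycles import DurationBank

    return DurationBank(
        {
            ("A", "nor"): np.array([90.0]),
            ("B", "nor"): np.array([90.0]),
            ("any", "nta"): np.array([240.0]),
            ("any", "sen"): np.array([240.0]),
        }
    )
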