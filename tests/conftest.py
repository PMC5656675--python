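import numpy as np
import pytest

from proppinlab.kinetics import LipidCondition, ObservableModel, RateParameters
from proppinlab.xlink import ProteinRecord


@pytest.fixture
def single_step_params() -> RateParameters:
    """Pure binding, no oligomerization (k_oli = k_dis = 0)."""
    return RateParameters(k_on=0.85, k_off=0.66)


@pytest.fixture
def two_step_params() -> RateParameters:
    return RateParameters(k_on=0.85, k_off=0.66, k_oli=0.2, k_dis=0.05)


@pytest.fixture
def bound_observable() -> ObservableModel:
    """Default readout: membrane-bound protein (B and O equally) fluoresces."""
    return ObservableModel()


@pytest.fixture
def condition() -> LipidCondition:
    return LipidCondition.from_accessible(0.3)


@pytest.fixture
def small_protein() -> ProteinRecord:
    # tryptic sites after K6, R12, K18; C-terminal tail without K/R
    return ProteinRecord(id="toy", sequence="MSTYAKGACDERGHILMKVPWN")
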