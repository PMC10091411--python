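import numpy as np
import pytest

from snokin import OperatingPoint, ProtonationModel, RateConstants
from snokin.synth import ScenarioConfig, published_scenario


@pytest.fixture
def k_published() -> RateConstants:
    """Rate constants at the published 5 degC AcCys operating point (with the
    package-default placeholders for the unpublished ferric thiol-binding pair)."""
    return RateConstants(
        k_on_RS=1e4, k_off_RS=20.0, k_on_NO=3.7e6, k_off_NO=3.4,
        k_on_RSminus=6.32e6, k_off_RSminus=5.9, k2=0.0,
    )


@pytest.fixture
def accys_model() -> ProtonationModel:
    return ProtonationModel({278.15: 9.95}, thiol="AcCys")


@pytest.fixture
def gsh_model() -> ProtonationModel:
    return ProtonationModel({278.15: 9.32}, thiol="GSH")


@pytest.fixture
def op_fig3() -> OperatingPoint:
    """Pathway-1 operating point: 3 mM total thiol, mid-range NO."""
    return OperatingPoint(no=8e-4, rs_total=3e-3, ph=7.4, temperature=278.15)


@pytest.fixture
def scenario() -> ScenarioConfig:
    return published_scenario(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
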