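import pytest

from bionicvein import ImplantType, ParameterSet
from bionicvein.templates import load_parameter_table, packaged_table_path


@pytest.fixture
def t_values() -> dict:
    """A valid T-plate parameter dictionary (satisfies every relation)."""
    return dict(
        h1=40.0, l1=8.0, m1=8.0, l2=12.0, m2=12.0,
        u1=4.0, t1=4.0, u2=4.0, t2=4.0,
        alpha1=120.0, alpha2=120.0, n1=4.0, d1=3.0,
    )


@pytest.fixture
def t_params(t_values) -> ParameterSet:
    return ParameterSet(ImplantType.T_PLATE, t_values)


@pytest.fixture
def l_params() -> ParameterSet:
    return ParameterSet(
        ImplantType.L_PLATE_LEFT,
        dict(h2=35.0, l3=7.0, m3=7.0, l4=15.0, m4=8.0, u3=4.0, t3=4.0, gamma3=1.0),
    )


@pytest.fixture(scope="session")
def clover_rows() -> list[ParameterSet]:
    return load_parameter_table(packaged_table_path(1), ImplantType.CLOVER_HEAD)


@pytest.fixture(scope="session")
def stem_rows() -> list[ParameterSet]:
    return load_parameter_table(packaged_table_path(2), ImplantType.FEMORAL_STEM_REGION)
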