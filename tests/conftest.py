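import pytest

from lipiduvpd import AcylChain, build_lipid_ion
from lipiduvpd.chem import CYCLOPROPANE, DOUBLE_BOND


@pytest.fixture
def pe341_proton():
    """PE 16:0/18:1 [M+H]+ with the double bond localized at Δ11."""
    return build_lipid_ion(
        "PE",
        [AcylChain(16, 0, sn=1), AcylChain(18, 1, ((DOUBLE_BOND, 11),), sn=2)],
        "+H",
    )


@pytest.fixture
def pe341_proton_bare():
    """PE 16:0_18:1 [M+H]+ at chain-composition level (no located mods)."""
    return build_lipid_ion("PE", [AcylChain(16, 0), AcylChain(18, 1)], "+H")


@pytest.fixture
def pe331_deprot():
    """PE 16:0_17:1(cy9) [M-H]-."""
    return build_lipid_ion(
        "PE",
        [AcylChain(16, 0), AcylChain(17, 1, ((CYCLOPROPANE, 9),))],
        "-H",
    )


@pytest.fixture
def pg372_deprot():
    """PG 18:1(Δ11)_19:1(cy11) [M-H]-."""
    return build_lipid_ion(
        "PG",
        [
            AcylChain(18, 1, ((DOUBLE_BOND, 11),)),
            AcylChain(19, 1, ((CYCLOPROPANE, 11),)),
        ],
        "-H",
    )


@pytest.fixture
def cdl724_deprot():
    """CDL 72:4 (4 x 18:1(Δ11)) [M-H]-."""
    return build_lipid_ion(
        "CDL", [AcylChain(18, 1, ((DOUBLE_BOND, 11),))] * 4, "-H"
    )
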