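import pytest
from hypothesis import settings

from g4ims.mobility import DriftTubeConfig
from g4ims.sequences import parse_shorthand

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

#: The five 60-mer constructs: shorthand, G4 subunits, declared inner NH4+.
TABLE1 = {
    "G4Tn": ("dT(TG3)4T43·(NH4+)2", 1, 2),
    "TnG4": ("dT43T(TG3)4·(NH4+)2", 1, 2),
    "TnG4Tn": ("dT21T(TG3)4T22·(NH4+)2", 1, 2),
    "G4TnG4": ("dT(TG3)4T26T(TG3)4·(NH4+)4", 2, 4),
    "NG": ("dT4GT5TGT4(GT3)5(GT2)2GT4TGT4GT4T2", 0, None),
}


@pytest.fixture(scope="session")
def table1():
    return {
        name: parse_shorthand(sh, name=name) for name, (sh, _, _) in TABLE1.items()
    }


@pytest.fixture(scope="session")
def g4tn(table1):
    return table1["G4Tn"]


@pytest.fixture(scope="session")
def cfg():
    return DriftTubeConfig()
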