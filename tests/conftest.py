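import numpy as np
import pytest

from tcellflux.emu_engine import TracerSpec
from tcellflux.ms_processing import load_fragment_library
from tcellflux.network_model import FluxState, load_builtin_model, parse_model

CHAIN_MODEL_TEXT = """
[metabolites]
A.x  carbons=2  balanced=no
B.c  carbons=2  balanced=yes
C.c  carbons=2  balanced=yes
D.x  carbons=2  balanced=no

[reactions]
v1: A.x (ab) -> B.c (ab)
v2: B.c (ab) -> C.c (ba)  reversible
v3: C.c (ab) -> D.x (ab)
"""

CONDENSATION_MODEL_TEXT = """
[metabolites]
A.x  carbons=2  balanced=no
B.c  carbons=2  balanced=yes
C.c  carbons=4  balanced=yes
D.c  carbons=2  balanced=yes
E.c  carbons=2  balanced=yes
W.x  carbons=2  balanced=no

[reactions]
vin:  A.x (ab) -> B.c (ab)
cond: B.c (ab) + B.c (cd) -> C.c (abcd)
clv:  C.c (abcd) -> D.c (ab) + E.c (cd)
dout: D.c (ab) -> W.x (ab)
eout: E.c (ab) -> W.x (ab)
"""

# small cycle exercising mixing, dilution, CO2 release and rotational
# symmetry variants; 12 tracked carbons total
CYCLE_MODEL_TEXT = """
[metabolites]
A.x    carbons=2  balanced=no
P.c    carbons=2  balanced=yes
P.m    carbons=2  balanced=yes
P.obs  carbons=2  balanced=no
C1.m   carbons=1  balanced=yes
M.m    carbons=3  balanced=yes
F.m    carbons=2  balanced=yes
G.m    carbons=2  balanced=yes
CO2.u  carbons=1  balanced=no
CO2.x  carbons=1  balanced=no
O.x    carbons=2  balanced=no

[reactions]
upt:    A.x (ab) -> P.c (ab)
tr:     P.c (ab) -> P.m (ab)  kind=transport
mixp:   P.c (ab) + P.m (ab) -> P.obs (ab)  kind=mixing
cx:     P.m (ab) + C1.m (c) -> M.m (abc)
dec:    M.m (abc) -> F.m (bc) + C1.m (a)
fv:     F.m (ab) -> G.m (ab)  reversible
fv:     F.m (ab) -> G.m (ba)  reversible
gout:   G.m (ab) -> O.x (ab)
co2d:   CO2.u (a) -> C1.m (a)  kind=dilution
co2out: C1.m (a) -> CO2.x (a)
"""


def chain_flux(v=5.0, exch=2.0):
    return FluxState(
        net={"v1": v, "v2": v, "v3": v}, exchange={"v2": exch}
    )


def condensation_flux(v=4.0):
    return FluxState(
        net={"vin": 2 * v, "cond": v, "clv": v, "dout": v, "eout": v}
    )


def cycle_flux(upt=6.0, co2d=2.0, exch=1.5, mix=0.7):
    return FluxState(
        net={
            "upt": upt, "tr": upt, "cx": upt, "dec": upt, "fv": upt,
            "gout": upt, "co2d": co2d, "co2out": co2d,
        },
        exchange={"fv": exch},
        mixing={"P.obs": mix},
    )


def two_carbon_tracer(frac_labeled=0.75, purity=0.99):
    return TracerSpec(
        metabolite="A.x",
        components=(("11", frac_labeled), ("00", 1 - frac_labeled)),
        purity=purity,
    )


@pytest.fixture(scope="session")
def builtin_model():
    return load_builtin_model()


@pytest.fixture(scope="session")
def fragment_library():
    return load_fragment_library()


@pytest.fixture(scope="session")
def chain_model():
    return parse_model(CHAIN_MODEL_TEXT, tracer_species="A.x")


@pytest.fixture(scope="session")
def condensation_model():
    return parse_model(CONDENSATION_MODEL_TEXT, tracer_species="A.x")


@pytest.fixture(scope="session")
def cycle_model():
    return parse_model(CYCLE_MODEL_TEXT, tracer_species="A.x")
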