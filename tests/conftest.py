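import numpy as np
import pytest

from caflex.synthetic import make_geometry


def atom_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    x,
    y,
    z,
    record="ATOM",
    altloc=" ",
    icode=" ",
    b=10.0,
):
    """Hand-rolled fixed-column PDB record for parser tests."""
    padded = " " + name if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {padded:<4}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}"
        f"          {name[0]:>2}"
    )


@pytest.fixture(scope="session")
def helix20():
    return make_geometry(20, "ideal-helix")


@pytest.fixture(scope="session")
def helix41():
    return make_geometry(41, "ideal-helix")


@pytest.fixture(scope="session")
def two_domain41():
    return make_geometry(41, "two-domain")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
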