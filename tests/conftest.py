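import numpy as np
import pytest
from hypothesis import settings

from fxivar import fxi
from fxivar.census import load_census
from fxivar.structure import Structure
from fxivar.synthetic import make_helix, make_packed_pair

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundled_census():
    return load_census(fxi.bundled_census_path())


@pytest.fixture(scope="session")
def domain_map():
    return fxi.FXI_DOMAIN_MAP


@pytest.fixture(scope="session")
def toy_helix():
    return make_helix(12)


@pytest.fixture(scope="session")
def packed_pair_chains():
    return make_packed_pair(make_helix(12), make_helix(12), gap=0.5, as_chains=True)


@pytest.fixture(scope="session")
def packed_pair_domains():
    return make_packed_pair(make_helix(12), make_helix(12), gap=0.5, as_chains=False)


def single_atom(radius: float = 1.7, element: str = "C") -> Structure:
    return Structure(
        chain=np.array(["A"], object),
        resnum=np.array([1]),
        resname=np.array(["ALA"], object),
        atom_name=np.array(["CA"], object),
        element=np.array([element], object),
        xyz=np.zeros((1, 3)),
        radius=np.array([radius]),
    )


def structure_from_points(points, radius=1.7, resnums=None) -> Structure:
    points = np.asarray(points, float)
    n = len(points)
    resnums = np.asarray(resnums if resnums is not None else np.arange(1, n + 1))
    return Structure(
        chain=np.array(["A"] * n, object),
        resnum=resnums,
        resname=np.array(["ALA"] * n, object),
        atom_name=np.array(["CA"] * n, object),
        element=np.array(["C"] * n, object),
        xyz=points,
        radius=np.full(n, radius, float),
    )
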