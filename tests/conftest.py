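import numpy as np
import pytest

from poremode.structure_io import AtomRecord, StructureModel
from poremode.synthetic_data import BundleSpec, dimer_network, make_helical_dimer
from poremode.enm import build_network, compute_modes


def random_ca_structure(n: int, seed: int, box: float = 15.0) -> StructureModel:
    """A compact random Cα cloud; dense contacts at cutoff 15 give exactly
    six rigid-body zero modes."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, (n, 3))
    atoms = [
        AtomRecord(serial=i + 1, name="CA", resname="ALA", chain="A", resid=i + 1,
                   coords=coords[i], element="C")
        for i in range(n)
    ]
    return StructureModel(atoms)


@pytest.fixture(scope="session")
def dimer():
    """The synthetic two-protomer bundle with its gating pairs and planted
    opening-mode description (soft interface, scale 0.05)."""
    return make_helical_dimer(BundleSpec(seed=0))


@pytest.fixture(scope="session")
def dimer_modes(dimer):
    structure, _, desc = dimer
    net = dimer_network(structure, desc["interface_spring_scale"], cutoff=13.0)
    return compute_modes(net, n_modes=100)


@pytest.fixture(scope="session")
def small_system():
    """30-site random structure with its elastic network and modes."""
    s = random_ca_structure(30, seed=42)
    net = build_network(s, cutoff=15.0)
    modes = compute_modes(net, n_modes=20)
    return s, net, modes
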