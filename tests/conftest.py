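import numpy as np
import pytest

from cspkit.energy import ForceField, PairParams, TorsionTerm
from cspkit.structures import CrystalStructure, UnitCell
from cspkit.synthetic import make_ionic_reference, make_toy_molecule


@pytest.fixture(scope="session")
def lj_ff():
    """Chargeless carbon-chain LJ force field."""
    return ForceField(pairs={("C", "C"): PairParams(0.5, 3.4)},
                      torsions={"default": TorsionTerm(3, 6.0, 0.0)},
                      real_cutoff=9.0)


@pytest.fixture(scope="session")
def rigid_mol():
    return make_toy_molecule(0, seed=2, charge_scale=0.0)


@pytest.fixture(scope="session")
def flexible_mol():
    return make_toy_molecule(2, seed=3, charge_scale=0.0)


@pytest.fixture(scope="session")
def ionic_ref():
    return make_ionic_reference(2.0)


@pytest.fixture
def p1_structure(rigid_mol):
    """Loose triclinic P1 packing of the rigid 3-atom toy."""
    return CrystalStructure(
        cell=UnitCell(7.5, 6.5, 6.0, 85.0, 95.0, 90.0), space_group=1,
        molecule=rigid_mol, position=np.array([0.1, 0.2, 0.3]),
        orientation=np.array([1.0, 0, 0, 0]), label="p1-toy")


@pytest.fixture(scope="session")
def single_site_structure():
    """One LJ site in P1: interactions only along short cell directions."""
    from cspkit.structures import Molecule
    mol = Molecule(elements=["Ar"], masses=np.array([39.948]),
                   charges=np.array([0.0]), coords=np.zeros((1, 3)))
    return CrystalStructure(
        cell=UnitCell(4.6, 40.0, 40.0), space_group=1, molecule=mol,
        position=np.zeros(3), orientation=np.array([1.0, 0, 0, 0]),
        label="1d-lj")


@pytest.fixture(scope="session")
def argon_ff():
    return ForceField(pairs={("Ar", "Ar"): PairParams(1.0, 3.4)},
                      real_cutoff=7.0)
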