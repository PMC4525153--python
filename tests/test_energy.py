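import numpy as np
import pytest

from cspkit.constants import GPA_A3_TO_KJ_MOL
from cspkit.energy import (CellAtoms, EwaldNeutralityError, ForceField,
                           PairParams, TorsionTerm, cell_atoms, cell_forces,
                           coulomb_ewald, enthalpy, fit_force_field,
                           lattice_energy, read_force_field, replicate_cell,
                           repulsion_dispersion, torsion_energy,
                           write_force_field)
from cspkit.structures import (CrystalStructure, Molecule, UnitCell,
                               cell_volume)
from cspkit.symmetry import get_setting
from cspkit.synthetic import (madelung_direct_sum, make_fit_dataset,
                              make_ionic_reference, make_toy_molecule)


class TestEwald:
    def test_matches_direct_sum_oracle_across_split_parameters(self, ionic_ref):
        """Ewald equals the converged Evjen direct sum, alpha-independently."""
        oracle = madelung_direct_sum(ionic_ref.d, n_shells=50)
        atoms = cell_atoms(ionic_ref.structure, ionic_ref.force_field)
        for alpha in (0.35, 0.7, 1.4):
            e_pair = coulomb_ewald(atoms, ionic_ref.force_field,
                                   alpha=alpha) / ionic_ref.n_pairs
            assert e_pair == pytest.approx(oracle, abs=1e-4)

    def test_bundled_energy_is_the_madelung_value(self, ionic_ref):
        oracle = madelung_direct_sum(ionic_ref.d, n_shells=50)
        assert ionic_ref.energy_per_pair == pytest.approx(oracle, abs=1e-4)

    def test_coulomb_scaling_with_distance(self):
        e1 = make_ionic_reference(2.0).energy_per_pair
        e2 = make_ionic_reference(4.0).energy_per_pair
        assert e1 / e2 == pytest.approx(2.0, rel=1e-12)

    def test_non_neutral_cell_refused(self):
        mol = Molecule(elements=["Na"], masses=np.array([23.0]),
                       charges=np.array([1.0]), coords=np.zeros((1, 3)),
                       net_charge=1.0)
        s = CrystalStructure(cell=UnitCell(6, 6, 6), space_group=1,
                             molecule=mol, position=np.zeros(3),
                             orientation=np.array([1.0, 0, 0, 0]))
        ff = ForceField(pairs={("Na", "Na"): PairParams(0.1, 2.4)})
        with pytest.raises(EwaldNeutralityError):
            lattice_energy(s, ff)


class TestRepulsionDispersion:
    def test_isolated_pair_minimum_is_minus_epsilon(self):
        sig, eps = 3.0, 1.25
        atoms = CellAtoms(
            M=np.eye(3) * 60.0,
            cart=np.array([[0.0, 0, 0], [2 ** (1 / 6) * sig, 0, 0]]),
            charges=np.zeros(2), elements=["Ar", "Ar"],
            mol_index=np.array([0, 1]), exclusions=[], n_molecules=2)
        ff = ForceField(pairs={("Ar", "Ar"): PairParams(eps, sig)},
                        real_cutoff=10.0)
        assert repulsion_dispersion(atoms, ff) == pytest.approx(-eps, rel=1e-12)

    def test_extensivity_under_supercell(self, ionic_ref):
        ff = ionic_ref.force_field
        atoms = cell_atoms(ionic_ref.structure, ff)
        alpha = 0.8  # common split so both descriptions sum identically
        e1 = repulsion_dispersion(atoms, ff) + coulomb_ewald(atoms, ff, alpha=alpha)
        sup = replicate_cell(atoms, (2, 1, 1))
        e2 = repulsion_dispersion(sup, ff) + coulomb_ewald(sup, ff, alpha=alpha)
        assert e2 / 2 == pytest.approx(e1, abs=1e-6)

    def test_intramolecular_exclusions(self, lj_ff):
        """1-2/1-3 pairs contribute nothing; 1-4 is scaled by 0.5."""
        mol = make_toy_molecule(1, seed=0, charge_scale=0.0)  # 4-atom chain
        s = CrystalStructure(cell=UnitCell(30, 30, 30), space_group=1,
                             molecule=mol, position=np.array([0.5, 0.5, 0.5]),
                             orientation=np.array([1.0, 0, 0, 0]),
                             torsion_angles=np.array([180.0]))
        full = ForceField(pairs=lj_ff.pairs, torsions={}, real_cutoff=9.0,
                          scale_14=1.0)
        none = ForceField(pairs=lj_ff.pairs, torsions={}, real_cutoff=9.0,
                          scale_14=0.0)
        half = ForceField(pairs=lj_ff.pairs, torsions={}, real_cutoff=9.0,
                          scale_14=0.5)
        e_full = lattice_energy(s, full).repdisp
        e_none = lattice_energy(s, none).repdisp
        e_half = lattice_energy(s, half).repdisp
        assert e_half == pytest.approx((e_full + e_none) / 2, abs=1e-12)
        assert e_full != pytest.approx(e_none)


class TestForces:
    def test_analytic_forces_match_central_differences(self, ionic_ref):
        rng = np.random.default_rng(11)
        ff = ionic_ref.force_field
        atoms = cell_atoms(ionic_ref.structure, ff)
        atoms.cart = atoms.cart + rng.normal(0.0, 0.12, atoms.cart.shape)
        f_an = cell_forces(atoms, ff)
        h = 1e-5

        def energy(cart):
            a = CellAtoms(M=atoms.M, cart=cart, charges=atoms.charges,
                          elements=atoms.elements, mol_index=atoms.mol_index,
                          exclusions=atoms.exclusions,
                          n_molecules=atoms.n_molecules)
            return repulsion_dispersion(a, ff) + coulomb_ewald(a, ff)

        f_fd = np.zeros_like(f_an)
        for i in range(atoms.n_atoms):
            for k in range(3):
                cp, cm = atoms.cart.copy(), atoms.cart.copy()
                cp[i, k] += h
                cm[i, k] -= h
                f_fd[i, k] = -(energy(cp) - energy(cm)) / (2 * h)
        scale = np.max(np.abs(f_fd))
        assert np.max(np.abs(f_an - f_fd)) / scale < 1e-4


class TestEnthalpy:
    def test_zero_pressure_is_lattice_energy(self, p1_structure, lj_ff):
        assert enthalpy(p1_structure, lj_ff, 0.0) == pytest.approx(
            lattice_energy(p1_structure, lj_ff).total, abs=1e-12)

    def test_pv_term_unit_conversion(self, p1_structure, lj_ff):
        # 1 GPa x 100 Å^3 = 60.2214 kJ/mol
        assert 1.0 * 100.0 * GPA_A3_TO_KJ_MOL == pytest.approx(60.2214, abs=1e-4)
        v_mol = cell_volume(p1_structure.cell) / get_setting(1).multiplicity
        h = enthalpy(p1_structure, lj_ff, 1.0)
        e = lattice_energy(p1_structure, lj_ff).total
        assert h - e == pytest.approx(v_mol * GPA_A3_TO_KJ_MOL, rel=1e-12)

    def test_larger_volume_larger_enthalpy(self, rigid_mol, lj_ff):
        def at_volume(a):
            return CrystalStructure(
                cell=UnitCell(a, a, a), space_group=1, molecule=rigid_mol,
                position=np.zeros(3), orientation=np.array([1.0, 0, 0, 0]))
        p = 0.5
        h_small = enthalpy(at_volume(8.0), lj_ff, p) - lattice_energy(at_volume(8.0), lj_ff).total
        h_large = enthalpy(at_volume(9.0), lj_ff, p) - lattice_energy(at_volume(9.0), lj_ff).total
        assert h_large > h_small

    def test_negative_pressure_rejected(self, p1_structure, lj_ff):
        with pytest.raises(ValueError, match="negative pressure"):
            enthalpy(p1_structure, lj_ff, -0.1)


class TestBreakdown:
    def test_components_sum_to_total(self, p1_structure, lj_ff):
        bd = lattice_energy(p1_structure, lj_ff, pressure=0.3)
        assert bd.total == pytest.approx(
            bd.repdisp + bd.coulomb + bd.torsion + bd.pv, abs=1e-9)

    def test_pv_zero_at_zero_pressure(self, p1_structure, lj_ff):
        assert lattice_energy(p1_structure, lj_ff).pv == 0.0

    def test_torsion_term_value(self):
        mol = make_toy_molecule(1, seed=0)
        ff = ForceField(pairs={("C", "C"): PairParams(0.5, 3.4)},
                        torsions={"default": TorsionTerm(3, 6.0, 0.0)})
        # (V/2)(1+cos(3*phi)): minima at 60/180/300, maxima at 0/120/240
        assert torsion_energy(mol, [60.0], ff) == pytest.approx(0.0, abs=1e-12)
        assert torsion_energy(mol, [180.0], ff) == pytest.approx(0.0, abs=1e-12)
        assert torsion_energy(mol, [0.0], ff) == pytest.approx(6.0, abs=1e-12)


@pytest.fixture(scope="module")
def truth():
    return ForceField(pairs={("C", "C"): PairParams(0.55, 3.45)},
                      torsions={"default": TorsionTerm(3, 5.0, 0.0)},
                      real_cutoff=9.0)


class TestFit:

    def test_fixed_point_residual_zero(self, truth):
        ds = make_fit_dataset(truth, n_structures=12, noise=0.0, seed=1)
        fitted = fit_force_field(ds.reference, truth)
        assert fitted.provenance["residual_rms"] == pytest.approx(0.0, abs=1e-8)
        assert fitted.pairs[("C", "C")].epsilon == pytest.approx(0.55, rel=1e-6)
        assert fitted.pairs[("C", "C")].sigma == pytest.approx(3.45, rel=1e-6)

    def test_parameter_recovery_from_perturbed_start(self, truth):
        ds = make_fit_dataset(truth, n_structures=50, noise=0.0, seed=2)
        start = ForceField(pairs={("C", "C"): PairParams(0.75, 3.2)},
                           torsions={"default": TorsionTerm(3, 7.5, 0.0)},
                           real_cutoff=9.0)
        fitted = fit_force_field(ds.reference, start)
        assert fitted.pairs[("C", "C")].epsilon == pytest.approx(0.55, rel=0.01)
        assert fitted.pairs[("C", "C")].sigma == pytest.approx(3.45, rel=0.01)
        assert fitted.torsions["default"].barrier == pytest.approx(5.0, rel=0.01)
        assert fitted.provenance["origin"] == "fitted"

    def test_constant_shift_absorbed_by_offset(self, truth):
        ds = make_fit_dataset(truth, n_structures=20, noise=0.0, seed=3)
        shifted = [(s, e + 7.5) for s, e in ds.reference]
        fitted = fit_force_field(shifted, truth, fit_offset=True)
        assert fitted.energy_offset == pytest.approx(7.5, abs=1e-4)
        assert fitted.pairs[("C", "C")].epsilon == pytest.approx(0.55, rel=1e-3)
        assert fitted.pairs[("C", "C")].sigma == pytest.approx(3.45, rel=1e-3)

    def test_noise_shows_up_as_residual(self, truth):
        ds = make_fit_dataset(truth, n_structures=30, noise=0.5, seed=4)
        fitted = fit_force_field(ds.reference, truth)
        assert 0.3 <= fitted.provenance["residual_rms"] <= 0.7

    def test_rank_deficient_fit_warns(self, truth):
        ds = make_fit_dataset(truth, n_structures=12, noise=0.0, seed=5)
        template = ForceField(
            pairs={("C", "C"): PairParams(0.55, 3.45),
                   ("Xe", "Xe"): PairParams(1.0, 4.0)},   # absent element
            torsions={"default": TorsionTerm(3, 5.0, 0.0)},
            real_cutoff=9.0)
        with pytest.warns(UserWarning, match="unconstrained"):
            fitted = fit_force_field(ds.reference, template)
        assert any("Xe" in name
                   for name in fitted.provenance["degenerate_parameters"])

    def test_too_few_reference_points_rejected(self, truth):
        ds = make_fit_dataset(truth, n_structures=2, noise=0.0, seed=6)
        with pytest.raises(ValueError, match="residuals"):
            fit_force_field(ds.reference, truth)


class TestForceFieldIO:
    def test_round_trip(self, tmp_path):
        ff = ForceField(pairs={("C", "C"): PairParams(0.5, 3.4, 120.0, 3.0)},
                        torsions={"default": TorsionTerm(3, 6.0, 60.0)},
                        real_cutoff=9.0, scale_14=0.4, energy_offset=1.5)
        p = tmp_path / "ff.yaml"
        write_force_field(ff, p)
        back = read_force_field(p)
        assert back.pairs[("C", "C")] == ff.pairs[("C", "C")]
        assert back.torsions["default"] == ff.torsions["default"]
        assert back.scale_14 == ff.scale_14
        assert back.energy_offset == ff.energy_offset
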