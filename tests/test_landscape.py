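import numpy as np
import pandas as pd
import pytest

from cspkit.constants import GPA_A3_TO_KJ_MOL
from cspkit.landscape import (DEFAULT_PRESSURE_GRID, build_landscape,
                              cluster_families, compare_rankings, deduplicate,
                              find_crossings, fingerprint_distance,
                              packing_fingerprint, pressure_scan,
                              structure_fingerprint)
from cspkit.structures import CrystalStructure, Molecule, UnitCell
from cspkit.symmetry import expand_asymmetric_unit
from cspkit.synthetic import make_family_pair


@pytest.fixture(scope="module")
def family_pair():
    return make_family_pair(seed=0)


def _labels_energies(fp):
    labels = [s.label for s in fp.structures]
    return labels, [fp.energies[l] for l in labels]


class TestFingerprint:
    def test_supercell_redescription_matches(self, family_pair):
        s = family_pair.structures[0]
        frac, _ = expand_asymmetric_unit(s, hard_core=0.0)
        centroids = frac.mean(axis=1)
        M = s.cell.matrix()
        f1 = packing_fingerprint(M, centroids)
        # 2x1x1 supercell description of the same packing
        M2 = M @ np.diag([2.0, 1.0, 1.0])
        c2 = np.vstack([centroids * [0.5, 1, 1],
                        centroids * [0.5, 1, 1] + [0.5, 0, 0]])
        f2 = packing_fingerprint(M2, c2)
        assert fingerprint_distance(f1, f2) < 1e-8

    def test_distinct_packings_differ(self, family_pair):
        fA = structure_fingerprint(family_pair.structures[0])
        fB = structure_fingerprint(family_pair.structures[3])
        assert fingerprint_distance(fA, fB) > 0.5


class TestDeduplicate:
    def test_structure_is_its_own_duplicate(self, family_pair):
        s = family_pair.structures[0]
        e = family_pair.energies[s.label]
        kept, rep = deduplicate([s, s], [e, e])
        assert len(kept) == 1

    def test_planted_duplicates_collapse(self, family_pair):
        labels, energies = _labels_energies(family_pair)
        kept, rep = deduplicate(family_pair.structures, energies)
        kept_labels = {labels[i] for i in kept}
        assert kept_labels == {"A1", "A2", "A3", "B1", "B2", "B3"}
        dup_idx = labels.index("A1-dup")
        assert labels[rep[dup_idx]] == "A1"

    def test_supercell_duplicate_via_fingerprints(self, family_pair):
        s = family_pair.structures[0]
        e = family_pair.energies[s.label]
        frac, _ = expand_asymmetric_unit(s, hard_core=0.0)
        centroids = frac.mean(axis=1)
        M = s.cell.matrix()
        f1 = packing_fingerprint(M, centroids)
        M2 = M @ np.diag([2.0, 1.0, 1.0])
        c2 = np.vstack([centroids * [0.5, 1, 1],
                        centroids * [0.5, 1, 1] + [0.5, 0, 0]])
        f2 = packing_fingerprint(M2, c2)
        kept, _ = deduplicate([s, s], [e, e + 1e-6], fingerprints=[f1, f2])
        assert len(kept) == 1

    def test_different_families_not_duplicates(self, family_pair):
        a = family_pair.structures[0]
        b = family_pair.structures[3]
        kept, _ = deduplicate([a, b],
                              [family_pair.energies[a.label]] * 2)
        assert len(kept) == 2


class TestClusterFamilies:
    def test_recovers_planted_partition(self, family_pair):
        labels, energies = _labels_energies(family_pair)
        kept, _ = deduplicate(family_pair.structures, energies)
        reps = [family_pair.structures[i] for i in kept]
        rep_l = [labels[i] for i in kept]
        rep_e = [energies[i] for i in kept]
        fams = cluster_families(reps, rep_e, rep_l)
        for x in rep_l:
            for y in rep_l:
                same_truth = (family_pair.true_families[x]
                              == family_pair.true_families[y])
                assert (fams[x] == fams[y]) == same_truth

    def test_families_named_after_lowest_energy_member(self, family_pair):
        labels, energies = _labels_energies(family_pair)
        kept, _ = deduplicate(family_pair.structures, energies)
        reps = [family_pair.structures[i] for i in kept]
        rep_l = [labels[i] for i in kept]
        rep_e = dict(zip(rep_l, (energies[i] for i in kept)))
        fams = cluster_families(reps, list(rep_e.values()), rep_l)
        for fam_name in set(fams.values()):
            members = [l for l in rep_l if fams[l] == fam_name]
            assert fam_name == min(members, key=lambda l: rep_e[l])

    def test_singleton_is_its_own_family(self, family_pair):
        s = family_pair.structures[0]
        fams = cluster_families([s], [0.0], [s.label])
        assert fams == {s.label: s.label}


def _dummy_structure(label, v_cell, mass=100.0):
    a = v_cell ** (1 / 3)
    mol = Molecule(elements=["X"], masses=np.array([mass]),
                   charges=np.array([0.0]), coords=np.zeros((1, 3)))
    return CrystalStructure(cell=UnitCell(a, a, a), space_group=1,
                            molecule=mol, position=np.zeros(3),
                            orientation=np.array([1.0, 0, 0, 0]), label=label)


class TestBuildLandscape:
    def test_mean_centering_and_ranks(self):
        structures = [_dummy_structure(l, v) for l, v in
                      [("s1", 150.0), ("s2", 160.0), ("s3", 170.0)]]
        df = build_landscape(structures, [-10.0, -8.0, -6.0], top_n=3)
        assert list(df["rel_energy"]) == pytest.approx([-2.0, 0.0, 2.0])
        assert list(df["rank"]) == [1, 2, 3]
        assert abs(df["rel_energy"].mean()) < 1e-9

    def test_single_entry_is_zero(self):
        df = build_landscape([_dummy_structure("s", 150.0)], [-5.0], top_n=1)
        assert df["rel_energy"].iloc[0] == pytest.approx(0.0)

    def test_shift_invariance(self):
        structures = [_dummy_structure(l, v) for l, v in
                      [("s1", 150.0), ("s2", 160.0), ("s3", 170.0)]]
        d1 = build_landscape(structures, [-10.0, -8.0, -6.0])
        d2 = build_landscape(structures, [90.0, 92.0, 94.0])
        assert np.allclose(d1["rel_energy"], d2["rel_energy"])
        assert list(d1["label"]) == list(d2["label"])

    def test_tie_broken_by_higher_density(self):
        dense = _dummy_structure("dense", 120.0)
        loose = _dummy_structure("loose", 200.0)
        df = build_landscape([loose, dense], [-5.0, -5.0])
        assert list(df["label"]) == ["dense", "loose"]

    def test_top_n_validation(self):
        with pytest.raises(ValueError, match="top_n"):
            build_landscape([_dummy_structure("s", 150.0)], [0.0], top_n=2)


def _synthetic_profiles(e_v_pairs, grid=None):
    """Profiles from H = E + p·V on fixed (E, V): pure arithmetic."""
    grid = DEFAULT_PRESSURE_GRID if grid is None else grid
    rows = []
    for label, (e, v) in e_v_pairs.items():
        for p in grid:
            rows.append({"label": label, "pressure": float(p),
                         "enthalpy": e + p * v * GPA_A3_TO_KJ_MOL,
                         "volume": v, "converged": True})
    df = pd.DataFrame(rows)
    for p, sub in df.groupby("pressure"):
        df.loc[sub.index, "rel_enthalpy"] = sub["enthalpy"] - sub["enthalpy"].mean()
    return df


class TestPressureProfilesArithmetic:
    def test_default_grid_has_six_points(self):
        assert len(DEFAULT_PRESSURE_GRID) == 6
        assert DEFAULT_PRESSURE_GRID[0] == 0.0
        assert DEFAULT_PRESSURE_GRID[-1] == 1.0
        assert np.allclose(np.diff(DEFAULT_PRESSURE_GRID), 0.2)

    def test_denser_higher_energy_structure_gains_under_pressure(self):
        # B: lower V, higher E than A -> relative H of B strictly decreases
        df = _synthetic_profiles({"A": (-10.0, 120.0), "B": (-8.0, 100.0)})
        rel_b = df[df.label == "B"].sort_values("pressure")["rel_enthalpy"]
        assert np.all(np.diff(rel_b) < 0)

    def test_linear_crossing_at_half_gpa(self):
        # ΔH from +1 at p=0 to -1 at p=1, linear
        grid = np.array([0.0, 1.0])
        df = _synthetic_profiles({"A": (0.0, 100.0)}, grid)
        dh = np.array([1.0, -1.0])
        df2 = df.copy()
        df2["label"] = "B"
        df2["enthalpy"] = df["enthalpy"].to_numpy() + dh
        both = pd.concat([df, df2])
        crossings = find_crossings(both, "A")
        assert crossings["B"] == pytest.approx([0.5], abs=1e-3)

    def test_analytic_crossing_pressure_recovered(self):
        e_a, v_a = -12.0, 130.0
        e_b, v_b = -9.5, 104.0
        p_star = (e_b - e_a) / ((v_a - v_b) * GPA_A3_TO_KJ_MOL)
        assert 0.0 < p_star < 1.0
        df = _synthetic_profiles({"A": (e_a, v_a), "B": (e_b, v_b)})
        crossings = find_crossings(df, "A")
        assert crossings["B"] == pytest.approx([p_star], abs=1e-3)

    def test_no_crossing_is_empty_not_error(self):
        df = _synthetic_profiles({"A": (-10.0, 120.0), "B": (-5.0, 125.0)})
        assert find_crossings(df, "A")["B"] == []

    def test_per_pressure_calibration_sums_to_zero(self):
        df = _synthetic_profiles({"A": (-10.0, 120.0), "B": (-8.0, 100.0),
                                  "C": (-6.0, 110.0)})
        for _, sub in df.groupby("pressure"):
            assert abs(sub["rel_enthalpy"].mean()) < 1e-9


class TestPressureScan:
    def test_scan_thermodynamics_and_zero_pressure_consistency(self, argon_ff):
        """V non-increasing and H concave along the grid; a single
        structure self-calibrates to a zero profile."""
        from cspkit.minimize import minimize_lattice
        mol = Molecule(elements=["Ar"], masses=np.array([39.948]),
                       charges=np.array([0.0]), coords=np.zeros((1, 3)))
        compact = CrystalStructure(
            cell=UnitCell(4.4, 4.6, 4.2, 85.0, 95.0, 92.0), space_group=1,
            molecule=mol, position=np.zeros(3),
            orientation=np.array([1.0, 0, 0, 0]), label="lj-crystal")
        base = minimize_lattice(compact, argon_ff).structure
        df = pressure_scan([base], argon_ff, grid=[0.0, 0.4, 0.8])
        assert df["converged"].all()
        v = df.sort_values("pressure")["volume"].to_numpy()
        h = df.sort_values("pressure")["enthalpy"].to_numpy()
        assert np.all(np.diff(v) <= 1e-8)
        assert np.all(np.diff(h) >= -1e-8)          # non-decreasing
        d2 = np.diff(h, 2)
        assert np.all(d2 <= 1e-6)                   # concave
        # single structure: self-calibration makes the profile zero
        assert np.allclose(df["rel_enthalpy"], 0.0, atol=1e-12)


class TestCompareRankings:
    def test_identical_rankings_deviate_zero(self):
        e = {"a": -1.0, "b": 0.5, "c": 2.0}
        cmp_ = compare_rankings(e, dict(e))
        assert cmp_.mean_abs_deviation == 0.0
        assert cmp_.mean_abs_deviation_raw == 0.0
        assert cmp_.rank_correlation == pytest.approx(1.0)

    def test_constant_offset_vanishes_after_centering(self):
        a = {"a": -1.0, "b": 0.5, "c": 2.0}
        b = {k: v + 3.7 for k, v in a.items()}
        cmp_ = compare_rankings(a, b)
        assert cmp_.mean_abs_deviation == pytest.approx(0.0, abs=1e-12)
        assert cmp_.mean_abs_deviation_raw == pytest.approx(3.7)

    def test_three_element_hand_computation(self):
        # centered lists {0,1,2} and {0,2,1}: |Δ| = {0,1,1} -> mean 2/3
        cmp_ = compare_rankings({"x": 0.0, "y": 1.0, "z": 2.0},
                                {"x": 0.0, "y": 2.0, "z": 1.0})
        assert cmp_.mean_abs_deviation == pytest.approx(2.0 / 3.0)

    def test_label_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="label mismatch.*'c'"):
            compare_rankings({"a": 0.0, "b": 1.0}, {"a": 0.0, "c": 1.0})
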