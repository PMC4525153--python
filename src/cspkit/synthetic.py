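"""Synthetic fixtures with bundled ground truth.

Everything the pipeline needs for testing is generated here from seeds:
chain-like toy molecules with a chosen number of rotatable torsions
(stand-ins for flexible drug-like molecules), a rock-salt ionic
reference crystal with its converged direct-sum Coulomb energy (the
Ewald oracle), reference datasets for tailor-made force-field fitting,
synthetic structure families with known partition, and small discrete /
torsional model systems with exactly enumerable Boltzmann statistics.

Regeneration from (kind, parameters, seed) is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from .constants import K_E, MADELUNG_NACL
from .energy import ForceField, PairParams, TorsionTerm, lattice_energy
from .structures import CrystalStructure, Molecule, Torsion, UnitCell

__all__ = [
    "make_toy_molecule",
    "make_ionic_reference",
    "madelung_direct_sum",
    "make_fit_dataset",
    "make_family_pair",
    "default_force_field",
    "DiscreteToy",
    "TorsionToy",
    "FitDataset",
    "FamilyPair",
]


def default_force_field(n_torsions: int = 0, charges: bool = True) -> ForceField:
    """A hand-set carbon-chain force field for the toy molecules."""
    pairs = {("C", "C"): PairParams(epsilon=0.5, sigma=3.4)}
    torsions = {"default": TorsionTerm(periodicity=3, barrier=6.0, phase=0.0)}
    if charges:
        pairs = dict(pairs)
    return ForceField(pairs=pairs, torsions=torsions, real_cutoff=9.0)


def make_toy_molecule(n_torsions: int, seed: int = 0,
                      charge_scale: float = 0.08) -> Molecule:
    """Chain-like neutral molecule with ``n_torsions`` rotatable bonds.

    The chain has ``n_torsions + 3`` carbon-like atoms in a planar
    zig-zag reference conformation (all dihedrals 180°); alternating
    partial charges of scale ``charge_scale`` are shifted to exact
    neutrality. ``seed`` applies a small deterministic geometric jitter
    so distinct seeds give distinct (but valid) molecules.
    """
    if n_torsions < 0:
        raise ValueError("n_torsions must be >= 0")
    n = n_torsions + 3
    rng = np.random.default_rng(seed)
    bond, theta = 1.53, math.radians(111.0)
    dx, dy = bond * math.sin(theta / 2), bond * math.cos(theta / 2)
    coords = np.array([[i * dx, (i % 2) * dy, 0.0] for i in range(n)])
    coords = coords + rng.normal(0.0, 0.01, coords.shape)
    charges = charge_scale * np.array([(-1.0) ** i for i in range(n)])
    charges -= charges.mean()
    bonds = [(i, i + 1) for i in range(n - 1)]
    torsions = [
        Torsion(atoms=(i, i + 1, i + 2, i + 3),
                moved=frozenset(range(i + 3, n)))
        for i in range(n - 3)
    ]
    return Molecule(
        elements=["C"] * n,
        masses=np.full(n, 12.011),
        charges=charges,
        coords=coords,
        bonds=bonds,
        torsions=torsions,
    )


# ---------------------------------------------------------------------------
# ionic reference crystal and the direct-sum Coulomb oracle


def madelung_direct_sum(d: float, n_shells: int = 12) -> float:
    """Direct-space Coulomb energy per ion pair of rock salt (kJ/mol).

    Evjen's method: charges on the boundary of the summation cube carry
    fractional weights, which makes each added shell charge-neutral and
    the partial sums converge rapidly. Independent of any Ewald code.
    """
    n = n_shells
    ax = np.arange(-n, n + 1)
    i, j, k = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(i * i + j * j + k * k, dtype=float) * d
    r[n, n, n] = np.inf  # exclude the central ion
    w = (np.where(np.abs(i) == n, 0.5, 1.0)
         * np.where(np.abs(j) == n, 0.5, 1.0)
         * np.where(np.abs(k) == n, 0.5, 1.0))
    sign = np.where((i + j + k) % 2 == 0, 1.0, -1.0)
    # lattice sum around one ion equals -M/d; the pair energy -M*k_e/d
    return K_E * float(np.sum(w * sign / r))


@dataclass
class IonicReference:
    """Rock-salt reference crystal plus its exact Coulomb energy."""

    structure: CrystalStructure
    force_field: ForceField
    energy_per_pair: float     # converged direct-sum oracle, kJ/mol
    n_pairs: int
    d: float


def make_ionic_reference(d: float = 2.0) -> IonicReference:
    """Rock-salt-analog crystal (±1 charges) with bundled Madelung energy.

    The conventional cubic cell (a = 2d, 4 formula units) is described in
    P1 with all eight ions as one rigid "molecule"; the bundled energy is
    the Evjen direct-sum value -M_NaCl * k_e / d per ion pair.
    """
    if d <= 0:
        raise ValueError("lattice spacing must be positive")
    a = 2.0 * d
    frac = np.array([
        [0, 0, 0], [0, .5, .5], [.5, 0, .5], [.5, .5, 0],      # cations
        [.5, 0, 0], [0, .5, 0], [0, 0, .5], [.5, .5, .5],      # anions
    ], dtype=float)
    charges = np.array([1.0] * 4 + [-1.0] * 4)
    cell = UnitCell(a, a, a)
    M = cell.matrix()
    cart = frac @ M.T
    centroid_frac = frac.mean(axis=0)
    mol = Molecule(
        elements=["Na"] * 4 + ["Cl"] * 4,
        masses=np.array([22.990] * 4 + [35.45] * 4),
        charges=charges,
        coords=cart - cart.mean(axis=0),
    )
    structure = CrystalStructure(
        cell=cell, space_group=1, molecule=mol,
        position=centroid_frac,
        orientation=np.array([1.0, 0, 0, 0]),
        label=f"rocksalt-d{d:g}",
    )
    ff = ForceField(pairs={
        ("Na", "Na"): PairParams(0.1, 2.4),
        ("Cl", "Cl"): PairParams(0.1, 3.4),
        ("Cl", "Na"): PairParams(0.1, 2.9),
    })
    return IonicReference(
        structure=structure,
        force_field=ff,
        energy_per_pair=-MADELUNG_NACL * K_E / d,
        n_pairs=4,
        d=d,
    )


# ---------------------------------------------------------------------------
# force-field fit datasets


@dataclass
class FitDataset:
    """Perturbed structures with energies from a known-truth force field."""

    reference: list            # [(structure, energy), ...]
    ff_true: ForceField
    noise: float
    seed: int


def make_fit_dataset(ff_true: ForceField, n_structures: int = 50,
                     noise: float = 0.0, seed: int = 0,
                     n_torsions: int = 1) -> FitDataset:
    """Reference set for tailor-made fitting, generated from ``ff_true``.

    P1 packings of a toy molecule with randomized cells, orientations
    and torsions; energies are ``ff_true`` values plus Gaussian noise of
    the stated scale. The ground-truth force field travels with the
    dataset.
    """
    rng = np.random.default_rng(seed)
    mol = make_toy_molecule(n_torsions, seed=seed, charge_scale=0.0)
    span = float(np.ptp(mol.coords[:, 0])) + 4.0
    reference = []
    attempts = 0
    while len(reference) < n_structures and attempts < 50 * n_structures:
        attempts += 1
        lengths = span * rng.uniform(0.85, 1.25, 3)
        angles = rng.uniform(80.0, 100.0, 3)
        try:
            cell = UnitCell(*lengths, *angles)
        except ValueError:
            continue
        q = Rotation.random(rng=rng).as_quat(scalar_first=True)
        s = CrystalStructure(
            cell=cell, space_group=1, molecule=mol,
            position=rng.uniform(0, 1, 3),
            orientation=q,
            torsion_angles=rng.uniform(0, 360, n_torsions),
            label=f"fit-{len(reference)}",
        )
        bd = lattice_energy(s, ff_true)
        if bd.overlap or bd.repdisp > 50.0:   # discard unphysical clashes
            continue
        e = bd.total + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        reference.append((s, e))
    if len(reference) < n_structures:
        raise RuntimeError("could not generate enough non-clashing structures")
    return FitDataset(reference=reference, ff_true=ff_true, noise=noise, seed=seed)


# ---------------------------------------------------------------------------
# structure families with known partition


@dataclass
class FamilyPair:
    """Two synthetic packing families with ground-truth labels."""

    structures: list
    energies: dict
    true_families: dict        # label -> "A" or "B"
    force_field: ForceField


def make_family_pair(seed: int = 0) -> FamilyPair:
    """Two P2_1/c toy-packing families plus planted exact duplicates.

    Within a family the members share cell, centroid and orientation and
    differ only in the tail torsion angle (conformational variants of one
    packing); the two families differ in cell and molecular placement —
    the analogue of chain neighbours related by a screw axis versus a
    glide plane. The lowest-energy member of each family is listed first.
    """
    mol = make_toy_molecule(1, seed=seed, charge_scale=0.0)
    ff = default_force_field()
    qa = Rotation.from_euler("xyz", [20.0, 35.0, 10.0], degrees=True
                             ).as_quat(scalar_first=True)
    qb = Rotation.from_euler("xyz", [75.0, -30.0, 55.0], degrees=True
                             ).as_quat(scalar_first=True)
    fam_a = dict(cell=UnitCell(8.6, 9.2, 10.4, 90.0, 101.0, 90.0),
                 position=np.array([0.16, 0.12, 0.21]), orientation=qa)
    fam_b = dict(cell=UnitCell(11.2, 7.6, 12.0, 90.0, 112.0, 90.0),
                 position=np.array([0.62, 0.36, 0.11]), orientation=qb)

    structures, energies, truth = [], {}, {}
    for fam, spec_, angles in (("A", fam_a, [178.0, 160.0, 196.0]),
                               ("B", fam_b, [181.0, 163.0, 199.0])):
        for i, ang in enumerate(angles, start=1):
            label = f"{fam}{i}"
            s = CrystalStructure(
                cell=spec_["cell"], space_group=14, molecule=mol,
                position=spec_["position"], orientation=spec_["orientation"],
                torsion_angles=np.array([ang]), label=label,
            )
            structures.append(s)
            energies[label] = lattice_energy(s, ff).total
            truth[label] = fam
    # planted exact duplicates of each family's first member
    for fam, spec_, ang in (("A", fam_a, 178.0), ("B", fam_b, 181.0)):
        label = f"{fam}1-dup"
        s = CrystalStructure(
            cell=spec_["cell"], space_group=14, molecule=mol,
            position=spec_["position"], orientation=spec_["orientation"],
            torsion_angles=np.array([ang]), label=label,
        )
        structures.append(s)
        energies[label] = lattice_energy(s, ff).total
        truth[label] = fam
    return FamilyPair(structures=structures, energies=energies,
                      true_families=truth, force_field=ff)


# ---------------------------------------------------------------------------
# exactly solvable sampler substrates


class DiscreteToy:
    """Finite state space with known Boltzmann distribution.

    Implements the sampler's system protocol: states are integers,
    proposals are uniform over all states (symmetric), and the partition
    function is computed by brute-force enumeration.
    """

    def __init__(self, energies):
        self.energies = np.asarray(energies, dtype=float)
        if self.energies.ndim != 1 or len(self.energies) < 2:
            raise ValueError("need at least two states")

    def initial_state(self, rng):
        return int(rng.integers(len(self.energies)))

    def energy(self, state):
        return float(self.energies[state])

    def propose(self, state, rng):
        return int(rng.integers(len(self.energies))), "jump"

    def quench(self, state):
        return state, self.energy(state)

    def key(self, state, energy):
        return state

    def boltzmann(self, temperature: float) -> np.ndarray:
        """Exact state probabilities at the given temperature (K)."""
        from .constants import K_B
        w = np.exp(-(self.energies - self.energies.min()) / (K_B * temperature))
        return w / w.sum()


class TorsionToy:
    """Separable two-torsion potential with a unique known global minimum.

    v(phi) = a (1 + cos phi) + b (1 + cos 3 phi) per torsion: the global
    minimum sits exactly at phi = 180 deg with v = 0, flanked by higher
    local minima near +-60 deg. Total energy is the sum over the two
    torsions, so the global minimum is (180, 180) with E = 0.
    """

    global_minimum = (180.0, 180.0)

    def __init__(self, a: float = 4.0, b: float = 2.5, step: float = 40.0):
        self.a, self.b, self.step = a, b, step

    def energy(self, state):
        phi = np.radians(np.asarray(state, dtype=float))
        return float(np.sum(self.a * (1 + np.cos(phi)) + self.b * (1 + np.cos(3 * phi))))

    def initial_state(self, rng):
        return rng.uniform(0.0, 360.0, 2)

    def propose(self, state, rng):
        i = int(rng.integers(2))
        new = np.array(state, dtype=float)
        new[i] = (new[i] + rng.normal(0.0, self.step)) % 360.0
        return new, "torsion"

    def quench(self, state):
        out = np.array(state, dtype=float)
        for i in range(2):
            res = minimize_scalar(
                lambda x, i=i: self.energy(np.where(np.arange(2) == i, x, out)),
                bounds=(out[i] - 60.0, out[i] + 60.0), method="bounded",
                options={"xatol": 1e-8})
            out[i] = res.x % 360.0
        return out, self.energy(out)

    def key(self, state, energy):
        return tuple(np.round(np.asarray(state) / 15.0).astype(int) % 24)
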