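"""Core data model: molecules, unit cells, crystal structures, CIF I/O.

Conventions
-----------
* Crystallographic Cartesian frame: ``a`` along x, ``b`` in the xy-plane.
* Fractional coordinates are column vectors; ``cart = M @ frac`` where the
  columns of ``M`` are the lattice vectors.
* One molecule per asymmetric unit (Z' = 1) throughout.
* Orientations are unit quaternions (scalar-first ``(w, x, y, z)``); CIF
  export always converts to explicit fractional atomic coordinates.
* Torsion angles follow the IUPAC sign convention: looking down the j->k
  bond, a positive angle rotates the far (l-side) branch clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .constants import N_A

__all__ = [
    "Torsion",
    "Molecule",
    "UnitCell",
    "CrystalStructure",
    "EnergyRecord",
    "cell_volume",
    "density",
    "dihedral_angle",
    "conformer_coordinates",
    "asymmetric_unit_coordinates",
    "read_molecule",
    "write_molecule",
    "read_cif",
    "write_cif",
]

DEFAULT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "S": 32.06, "Cl": 35.45, "Br": 79.904, "Ar": 39.948,
}


@dataclass(frozen=True)
class Torsion:
    """A rotatable single bond.

    ``atoms`` are the four indices (i, j, k, l) defining the dihedral;
    rotation is about the j->k bond and moves exactly the atoms in
    ``moved`` (a proper, connected subset that contains neither i nor j).
    ``type`` keys into the force field's torsion-term table.
    """

    atoms: tuple[int, int, int, int]
    moved: frozenset[int]
    type: str = "default"


@dataclass
class Molecule:
    """A flexible molecule: atoms, charges, bonded topology, torsions.

    ``coords`` holds the Cartesian reference conformation in Å; torsion
    angles are measured and applied relative to it.
    """

    elements: list[str]
    masses: np.ndarray
    charges: np.ndarray
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    torsions: list[Torsion] = field(default_factory=list)
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def mass(self) -> float:
        """Molecular mass in g/mol."""
        return float(self.masses.sum())

    def validate(self) -> None:
        n = self.n_atoms
        if not (len(self.masses) == len(self.charges) == len(self.coords) == n):
            raise ValueError("atom array lengths disagree")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
        if abs(self.charges.sum() - self.net_charge) > 1e-8:
            raise ValueError(
                f"total charge {self.charges.sum():g} != declared net charge "
                f"{self.net_charge:g}"
            )
        adj = _adjacency(n, self.bonds)
        for t in self.torsions:
            i, j, k, l = t.atoms
            for a in t.atoms:
                if not 0 <= a < n:
                    raise ValueError(f"torsion atom index {a} out of range")
            if i in t.moved or j in t.moved:
                raise ValueError("moved set may not contain the first two dihedral atoms")
            if not t.moved or len(t.moved) >= n:
                raise ValueError("moved set must be a proper, nonempty subset")
            if not _connected(t.moved, adj):
                raise ValueError("moved set must be connected in the bond graph")


def _adjacency(n: int, bonds: list[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _connected(subset: frozenset[int], adj: list[set[int]]) -> bool:
    subset = set(subset)
    stack = [next(iter(subset))]
    seen = {stack[0]}
    while stack:
        a = stack.pop()
        for b in adj[a] & subset:
            if b not in seen:
                seen.add(b)
                stack.append(b)
    return seen == subset


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise ValueError("degenerate cell: metric tensor not positive definite")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the lattice vectors (cart = M @ frac)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        sg = math.sin(math.radians(self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        v = math.sqrt(disc)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    def volume(self) -> float:
        return cell_volume(self)


def cell_volume(cell: UnitCell) -> float:
    """Cell volume in Å³ from the closed-form metric determinant."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0.0:
        raise ValueError("degenerate cell: metric tensor not positive definite")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


@dataclass
class CrystalStructure:
    """A Z' = 1 molecular crystal.

    The asymmetric unit is one molecule placed by its fractional centroid
    position, a unit quaternion orientation, and a vector of torsion
    angles (degrees, one per rotatable bond of the molecule).
    """

    cell: UnitCell
    space_group: int | str
    molecule: Molecule
    position: np.ndarray
    orientation: np.ndarray
    torsion_angles: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float) % 1.0
        q = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError("orientation quaternion must be normalized to 1e-10")
        self.orientation = q / norm
        if self.torsion_angles is None:
            self.torsion_angles = np.zeros(len(self.molecule.torsions))
        self.torsion_angles = np.asarray(self.torsion_angles, dtype=float)
        if len(self.torsion_angles) != len(self.molecule.torsions):
            raise ValueError("one torsion angle per rotatable bond required")

    def replace(self, **kw) -> "CrystalStructure":
        out = replace(self, **kw)
        return out


@dataclass(frozen=True)
class EnergyRecord:
    """A ranked structure's energetics: E, V per molecule, density, pressure."""

    label: str
    energy: float
    volume: float
    density: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume per molecule must be positive")

    @staticmethod
    def from_structure(structure: CrystalStructure, energy: float,
                       multiplicity: int, pressure: float = 0.0) -> "EnergyRecord":
        v_mol = cell_volume(structure.cell) / multiplicity
        rho = density(structure, multiplicity)
        return EnergyRecord(structure.label, energy, v_mol, rho, pressure)


def density(structure: CrystalStructure, Z: int) -> float:
    """Crystal density in g/cm³: Z·M / (N_A · V_cell), V_cell in Å³."""
    M = structure.molecule.mass
    if M <= 0:
        raise ValueError("zero-mass molecule")
    v_cm3 = cell_volume(structure.cell) * 1e-24
    return Z * M / (N_A * v_cm3)


# ---------------------------------------------------------------------------
# conformations


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees (IUPAC convention)."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.degrees(math.atan2(y, x))


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle_deg: float) -> np.ndarray:
    rot = Rotation.from_rotvec(axis / np.linalg.norm(axis) * math.radians(angle_deg))
    return rot.apply(points - origin) + origin


def conformer_coordinates(molecule: Molecule, torsion_angles: np.ndarray) -> np.ndarray:
    """Cartesian coordinates with each rotatable bond set to the given angle.

    Torsions are applied in list order; because each moved set is on one
    side of its bond this is well defined for chain-like topologies.
    """
    coords = molecule.coords.copy()
    for t, target in zip(molecule.torsions, np.asarray(torsion_angles, float)):
        i, j, k, l = t.atoms
        current = dihedral_angle(coords, i, j, k, l)
        delta = target - current
        if abs(delta) < 1e-14:
            continue
        # rotating the l-side atoms by +theta about (k - j) decreases the
        # dihedral in the sign convention above, hence -delta
        axis = coords[k] - coords[j]
        moved = sorted(t.moved)
        coords[moved] = _rotate_about_axis(coords[moved], coords[j], axis, -delta)
    return coords


def asymmetric_unit_coordinates(structure: CrystalStructure) -> np.ndarray:
    """Cartesian coordinates (Å) of the placed asymmetric-unit molecule."""
    conf = conformer_coordinates(structure.molecule, structure.torsion_angles)
    conf = conf - conf.mean(axis=0)
    rot = Rotation.from_quat(structure.orientation, scalar_first=True)
    M = structure.cell.matrix()
    centroid = M @ structure.position
    return rot.apply(conf) + centroid


# ---------------------------------------------------------------------------
# molecule file I/O (documented schema: see docs/methods.md)


def write_molecule(molecule: Molecule, path) -> None:
    doc = {
        "net_charge": float(molecule.net_charge),
        "atoms": [
            {
                "element": e,
                "mass": float(m),
                "charge": float(q),
                "xyz": [float(x) for x in xyz],
            }
            for e, m, q, xyz in zip(molecule.elements, molecule.masses,
                                    molecule.charges, molecule.coords)
        ],
        "bonds": [[int(i), int(j)] for i, j in molecule.bonds],
        "torsions": [
            {
                "atoms": [int(a) for a in t.atoms],
                "moved": sorted(int(a) for a in t.moved),
                "type": t.type,
            }
            for t in molecule.torsions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_molecule(path) -> Molecule:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    atoms = doc["atoms"]
    return Molecule(
        elements=[a["element"] for a in atoms],
        masses=np.array([a["mass"] for a in atoms]),
        charges=np.array([a["charge"] for a in atoms]),
        coords=np.array([a["xyz"] for a in atoms]),
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        torsions=[
            Torsion(tuple(t["atoms"]), frozenset(t["moved"]), t.get("type", "default"))
            for t in doc.get("torsions", [])
        ],
        net_charge=float(doc.get("net_charge", 0.0)),
    )


# ---------------------------------------------------------------------------
# CIF I/O


class CifError(ValueError):
    """Raised when a CIF file lacks required cell/coordinate items."""


def write_cif(structure: CrystalStructure, path) -> None:
    """Write the asymmetric unit as a small-molecule CIF.

    Orientation/torsions are baked into explicit fractional coordinates;
    point charges are carried in a ``_atom_site_charge`` column so that a
    read/write round trip is lossless for rigid molecules.
    """
    from .symmetry import get_setting  # local import to avoid a cycle

    setting = get_setting(structure.space_group)
    cell = structure.cell
    cart = asymmetric_unit_coordinates(structure)
    frac = np.linalg.solve(cell.matrix(), cart.T).T

    doc = gemmi.cif.Document()
    block = doc.add_new_block(structure.label or "cspkit")
    pairs = [
        ("_cell_length_a", f"{cell.a:.6f}"),
        ("_cell_length_b", f"{cell.b:.6f}"),
        ("_cell_length_c", f"{cell.c:.6f}"),
        ("_cell_angle_alpha", f"{cell.alpha:.6f}"),
        ("_cell_angle_beta", f"{cell.beta:.6f}"),
        ("_cell_angle_gamma", f"{cell.gamma:.6f}"),
        ("_space_group_IT_number", str(setting.number)),
        ("_symmetry_space_group_name_H-M", gemmi.cif.quote(setting.hermann_mauguin)),
    ]
    for tag, value in pairs:
        block.set_pair(tag, value)
    loop = block.init_loop("_symmetry_equiv_pos_", ["as_xyz"])
    for op in setting.operators:
        loop.add_row([gemmi.cif.quote(op.triplet())])
    loop = block.init_loop("_atom_site_", [
        "label", "type_symbol", "fract_x", "fract_y", "fract_z",
        "occupancy", "charge",
    ])
    for idx, (el, q, f) in enumerate(zip(structure.molecule.elements,
                                         structure.molecule.charges, frac)):
        loop.add_row([
            f"{el}{idx + 1}", el,
            f"{f[0]:.6f}", f"{f[1]:.6f}", f"{f[2]:.6f}",
            "1.0", f"{q:.6f}",
        ])
    doc.write_file(str(path))


def read_cif(path) -> CrystalStructure:
    """Read a CIF into a (rigid) CrystalStructure.

    The molecule is rebuilt from the atom sites with identity orientation
    and no bonded topology: CIF carries no unambiguous bond or torsion
    information, so structures read from CIF are treated as rigid bodies.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def _num(tag: str) -> float:
        raw = block.find_value(tag)
        if raw is None:
            raise CifError(f"missing required CIF item {tag}")
        return float(raw)

    cell = UnitCell(
        _num("_cell_length_a"), _num("_cell_length_b"), _num("_cell_length_c"),
        _num("_cell_angle_alpha"), _num("_cell_angle_beta"), _num("_cell_angle_gamma"),
    )
    sg: int | str | None = None
    number = block.find_value("_space_group_IT_number") or block.find_value(
        "_symmetry_Int_Tables_number")
    if number is not None:
        sg = int(number)
    else:
        symbol = block.find_value("_symmetry_space_group_name_H-M") or block.find_value(
            "_space_group_name_H-M_alt")
        if symbol is not None:
            sg = gemmi.cif.as_string(symbol)
        else:
            triplets = [gemmi.cif.as_string(v) for v in
                        block.find_loop("_symmetry_equiv_pos_as_xyz")]
            if triplets:
                ops = gemmi.GroupOps([gemmi.Op(t) for t in triplets])
                found = gemmi.find_spacegroup_by_ops(ops)
                if found is None:
                    raise CifError("symmetry operator list matches no space group")
                sg = found.number
    if sg is None:
        raise CifError("missing space-group item (_space_group_IT_number, "
                       "H-M symbol, or _symmetry_equiv_pos_as_xyz)")

    table = block.find("_atom_site_", ["type_symbol", "fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise CifError("missing _atom_site_ fractional coordinates")
    charges_col = block.find_loop("_atom_site_charge")
    charges = [float(v) for v in charges_col] if len(list(charges_col)) else None

    elements, frac = [], []
    for row in table:
        elements.append(gemmi.cif.as_string(row[0]))
        frac.append([float(gemmi.cif.as_string(row[i])) for i in (1, 2, 3)])
    frac = np.array(frac)
    if charges is None:
        charges = [0.0] * len(elements)

    M = cell.matrix()
    cart = (M @ frac.T).T
    centroid_frac = frac.mean(axis=0)
    ref = cart - cart.mean(axis=0)
    mol = Molecule(
        elements=elements,
        masses=np.array([DEFAULT_MASSES.get(e, 12.011) for e in elements]),
        charges=np.array(charges),
        coords=ref,
        net_charge=float(np.sum(charges)),
    )
    label = block.name if block.name != "cspkit" else ""
    return CrystalStructure(
        cell=cell, space_group=sg, molecule=mol,
        position=centroid_frac % 1.0,
        orientation=np.array([1.0, 0.0, 0.0, 0.0]),
        label=label,
    )
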