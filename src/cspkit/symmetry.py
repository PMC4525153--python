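"""Space-group table (all 230 groups) and Z'=1 symmetry expansion.

One canonical setting per international group number is used (standard
choice: unique axis b for monoclinic, origin choice 2 where applicable,
hexagonal axes for rhombohedral groups). The operator table comes from
gemmi's crystallographic tables; group-theoretic validation (closure,
identity, inverses modulo lattice translations) is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import gemmi
import numpy as np

from .structures import CrystalStructure, asymmetric_unit_coordinates

__all__ = [
    "SymOp",
    "SpaceGroupSetting",
    "get_setting",
    "enumerate_space_group_settings",
    "validate_group",
    "expand_asymmetric_unit",
    "lattice_system_constraints",
    "apply_lattice_constraints",
]

#: allowed translation denominators: all standard settings use n/12
_TRANSLATION_DEN = 12


@dataclass(frozen=True)
class SymOp:
    """A symmetry operator x' = R x + t in fractional coordinates.

    ``rot`` is a 3x3 integer matrix with entries in {-1, 0, 1}; ``tran``
    holds the translation as exact fractions.
    """

    rot: tuple[tuple[int, int, int], ...]
    tran: tuple[Fraction, Fraction, Fraction]

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.tran])

    def compose(self, other: "SymOp") -> "SymOp":
        """self applied after other: (R1, t1) * (R2, t2) = (R1 R2, R1 t2 + t1)."""
        r = self.rot_array @ other.rot_array
        t = [
            (sum(Fraction(self.rot[i][j]) * other.tran[j] for j in range(3))
             + self.tran[i]) % 1
            for i in range(3)
        ]
        return SymOp(tuple(tuple(int(x) for x in row) for row in r), tuple(t))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates of shape (..., 3)."""
        return frac @ self.rot_array.T + self.tran_array

    def triplet(self) -> str:
        parts = []
        for i in range(3):
            s = ""
            for j, axis in enumerate("xyz"):
                c = self.rot[i][j]
                if c == 1:
                    s += ("+" if s else "") + axis
                elif c == -1:
                    s += "-" + axis
            t = self.tran[i]
            if t:
                s += f"+{t.numerator}/{t.denominator}"
            parts.append(s or "0")
        return ",".join(parts)

    @staticmethod
    def identity() -> "SymOp":
        return SymOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)),
                     (Fraction(0), Fraction(0), Fraction(0)))


@dataclass(frozen=True)
class SpaceGroupSetting:
    """One canonical setting of a space group."""

    number: int
    hermann_mauguin: str
    operators: tuple[SymOp, ...]
    crystal_system: str

    @property
    def multiplicity(self) -> int:
        """Multiplicity Z of the general position."""
        return len(self.operators)


def _op_from_gemmi(op: gemmi.Op) -> SymOp:
    den = op.DEN
    rot = tuple(tuple(int(x) // den for x in row) for row in op.rot)
    tran = tuple(Fraction(int(t), den) % 1 for t in op.tran)
    return SymOp(rot, tran)


def get_setting(space_group: int | str) -> SpaceGroupSetting:
    """Look up the canonical setting by international number or H-M symbol."""
    if isinstance(space_group, int):
        sg = gemmi.find_spacegroup_by_number(space_group)
    else:
        sg = gemmi.SpaceGroup(space_group)
    if sg is None:
        raise ValueError(f"unknown space group {space_group!r}")
    ops = tuple(_op_from_gemmi(op) for op in sg.operations())
    return SpaceGroupSetting(sg.number, sg.hm, ops, sg.crystal_system_str())


def enumerate_space_group_settings() -> list[SpaceGroupSetting]:
    """All 230 groups, one canonical setting each, ordered by number."""
    return [get_setting(n) for n in range(1, 231)]


def validate_group(setting: SpaceGroupSetting) -> tuple[bool, list[str]]:
    """Check the operator list forms a group modulo lattice translations.

    Returns (ok, violations); violations name the offending operators.
    """
    violations: list[str] = []
    ops = setting.operators
    if not ops:
        return False, ["empty operator list"]
    den = _TRANSLATION_DEN
    for op in ops:
        for t in op.tran:
            if (t * den) % 1 != 0:
                violations.append(
                    f"operator '{op.triplet()}' has translation outside the "
                    f"n/{den} lattice")
    if violations:
        return False, violations

    # integer encoding: translations as numerators over den, mod den
    rots = np.array([op.rot for op in ops], dtype=int)
    trans = np.array([[int(t * den) % den for t in op.tran] for op in ops], dtype=int)
    keys = {}
    for i, (r, t) in enumerate(zip(rots, trans)):
        keys[(tuple(r.ravel()), tuple(t))] = i
    ident_key = (tuple(np.eye(3, dtype=int).ravel()), (0, 0, 0))
    if ident_key not in keys:
        violations.append("identity operator missing")
    has_inverse = set()
    n = len(ops)
    for a in range(n):
        # compose op a with every op b: (Ra, ta) * (Rb, tb) = (Ra Rb, Ra tb + ta)
        rc = np.einsum("ij,njk->nik", rots[a], rots)
        tc = (np.einsum("ij,nj->ni", rots[a], trans) + trans[a]) % den
        for b in range(n):
            key = (tuple(rc[b].ravel()), tuple(tc[b]))
            if key not in keys:
                violations.append(
                    f"closure violation: '{ops[a].triplet()}' * "
                    f"'{ops[b].triplet()}' leaves the set")
            if key == ident_key:
                has_inverse.add(a)
                has_inverse.add(b)
    for i in range(n):
        if i not in has_inverse:
            violations.append(f"no inverse for '{ops[i].triplet()}'")
    if setting.multiplicity != len(ops):
        violations.append("multiplicity does not match operator count")
    return (not violations), violations


def expand_asymmetric_unit(structure: CrystalStructure,
                           hard_core: float = 0.6):
    """Generate the full unit-cell contents from the Z'=1 asymmetric unit.

    Returns ``(frac, overlap_flag)`` where ``frac`` has shape
    (Z, n_atoms, 3): Z symmetry copies of the molecule, each image
    rigidly wrapped so its centroid lies in [0, 1).

    ``overlap_flag`` is True when any intermolecular atom-atom distance
    (over nearest periodic images) falls below ``hard_core`` Å; the
    expansion is still returned — callers decide how to treat clashes.
    """
    setting = get_setting(structure.space_group)
    M = structure.cell.matrix()
    cart = asymmetric_unit_coordinates(structure)
    frac0 = np.linalg.solve(M, cart.T).T

    images = []
    for op in setting.operators:
        img = op.apply(frac0)
        centroid = img.mean(axis=0)
        img = img - np.floor(centroid)
        images.append(img)
    frac = np.array(images)

    overlap = False
    if hard_core > 0 and len(images) > 1:
        shifts = np.array([[i, j, k] for i in (-1, 0, 1)
                           for j in (-1, 0, 1) for k in (-1, 0, 1)])
        for a in range(len(images)):
            for b in range(a + 1, len(images)):
                d = frac[a][:, None, :] - frac[b][None, :, :]
                d = d[:, :, None, :] + shifts[None, None, :, :]
                cart_d = np.einsum("ij,abkj->abki", M, d)
                if np.min(np.linalg.norm(cart_d, axis=-1)) < hard_core:
                    overlap = True
                    break
            if overlap:
                break
    return frac, overlap


# ---------------------------------------------------------------------------
# lattice-system cell constraints

_FREE_PARAMS = {
    "triclinic": ("a", "b", "c", "alpha", "beta", "gamma"),
    "monoclinic": ("a", "b", "c", "beta"),
    "orthorhombic": ("a", "b", "c"),
    "tetragonal": ("a", "c"),
    "trigonal": ("a", "c"),
    "hexagonal": ("a", "c"),
    "cubic": ("a",),
}


def lattice_system_constraints(setting: SpaceGroupSetting) -> tuple[str, ...]:
    """Names of the independent cell parameters for the lattice system."""
    return _FREE_PARAMS[setting.crystal_system]


def apply_lattice_constraints(setting: SpaceGroupSetting, values: dict) -> dict:
    """Full (a, b, c, alpha, beta, gamma) dict from the free parameters."""
    sysname = setting.crystal_system
    p = dict(a=values["a"], b=values.get("b", values["a"]),
             c=values.get("c", values["a"]),
             alpha=90.0, beta=90.0, gamma=90.0)
    if sysname == "triclinic":
        p.update(alpha=values["alpha"], beta=values["beta"], gamma=values["gamma"])
    elif sysname == "monoclinic":
        p.update(beta=values["beta"])
    elif sysname in ("trigonal", "hexagonal"):
        p.update(b=values["a"], gamma=120.0)
    elif sysname == "tetragonal":
        p.update(b=values["a"])
    elif sysname == "cubic":
        p.update(b=values["a"], c=values["a"])
    return p
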