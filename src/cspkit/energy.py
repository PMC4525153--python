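"""Classical lattice-energy surrogate and tailor-made force-field fitting.

The lattice energy per molecule is

    E = E_rep-disp + E_Coulomb + E_torsion

with a Lennard-Jones (plus optional Tang-Toennies-damped C6) site-site
term, point-charge electrostatics by Ewald summation, and cosine torsion
potentials for the rotatable bonds. Intramolecular nonbonded pairs are
excluded at 1-2/1-3 range and scaled at 1-4 range. The enthalpy under
hydrostatic pressure is H = E + p.V per molecule.

The "tailor-made" pattern — fit the pair and torsion parameters to a set
of reference energies (and optionally forces) for perturbed structures of
the molecule under study — is implemented in :func:`fit_force_field`.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.special import erfc

from .constants import GPA_A3_TO_KJ_MOL, K_E
from .structures import CrystalStructure, Molecule, cell_volume
from .symmetry import expand_asymmetric_unit, get_setting

__all__ = [
    "PairParams",
    "TorsionTerm",
    "ForceField",
    "EnergyBreakdown",
    "CellAtoms",
    "cell_atoms",
    "replicate_cell",
    "repulsion_dispersion",
    "coulomb_ewald",
    "cell_forces",
    "torsion_energy",
    "lattice_energy",
    "enthalpy",
    "stress_tensor",
    "fit_force_field",
    "read_force_field",
    "write_force_field",
    "EwaldNeutralityError",
]


class EwaldNeutralityError(ValueError):
    """Ewald summation requires a charge-neutral unit cell."""


@dataclass
class PairParams:
    """Repulsion-dispersion parameters for one element pair.

    ``epsilon`` (kJ/mol) and ``sigma`` (Å) are the LJ well depth and size;
    ``c6`` (kJ mol^-1 Å^6) adds a Tang-Toennies-damped dispersion term
    with damping parameter ``damping`` (Å^-1). c6 = 0 gives plain LJ.
    """

    epsilon: float
    sigma: float
    c6: float = 0.0
    damping: float = 0.0

    def validate(self) -> None:
        if self.epsilon < 0 or self.sigma <= 0 or self.c6 < 0:
            raise ValueError("require epsilon >= 0, sigma > 0, c6 >= 0")


@dataclass
class TorsionTerm:
    """Cosine torsion potential (V/2)(1 + cos(n*phi - phase))."""

    periodicity: int = 3
    barrier: float = 5.0
    phase: float = 0.0


@dataclass
class ForceField:
    """Pair, dispersion and torsion parameters plus Ewald settings.

    ``pairs`` maps sorted element tuples to :class:`PairParams`; missing
    cross pairs fall back to Lorentz-Berthelot combination of the
    homo-atomic entries. ``provenance`` records whether the parameters
    were hand-set or fitted, and with what residual.
    """

    pairs: dict[tuple[str, str], PairParams]
    torsions: dict[str, TorsionTerm] = field(default_factory=dict)
    real_cutoff: float = 10.0
    ewald_accuracy: float = 1e-5
    ewald_alpha: float | None = None
    scale_14: float = 0.5
    energy_offset: float = 0.0
    provenance: dict = field(default_factory=lambda: {"origin": "hand-set"})

    def __post_init__(self) -> None:
        self.pairs = {tuple(sorted(k)): v for k, v in self.pairs.items()}
        for p in self.pairs.values():
            p.validate()
        if self.real_cutoff <= 0 or self.ewald_accuracy <= 0:
            raise ValueError("cutoff and Ewald accuracy must be positive")

    def pair(self, e1: str, e2: str) -> PairParams:
        key = tuple(sorted((e1, e2)))
        if key in self.pairs:
            return self.pairs[key]
        try:
            p1 = self.pairs[(e1, e1)]
            p2 = self.pairs[(e2, e2)]
        except KeyError:
            raise KeyError(f"no pair parameters for {key}") from None
        return PairParams(
            epsilon=math.sqrt(p1.epsilon * p2.epsilon),
            sigma=0.5 * (p1.sigma + p2.sigma),
            c6=math.sqrt(p1.c6 * p2.c6),
            damping=0.5 * (p1.damping + p2.damping),
        )


@dataclass
class EnergyBreakdown:
    """Lattice energy per molecule, split into components.

    ``total`` is the exact sum of the components; ``pv`` is nonzero only
    when a pressure was applied. ``max_force`` and ``stress_residual``
    are filled by the minimizer's convergence check when requested.
    """

    repdisp: float
    coulomb: float
    torsion: float
    pv: float = 0.0
    overlap: bool = False
    max_force: float | None = None
    stress_residual: float | None = None

    @property
    def total(self) -> float:
        return self.repdisp + self.coulomb + self.torsion + self.pv


# ---------------------------------------------------------------------------
# unit-cell atom lists


@dataclass
class CellAtoms:
    """Flat description of one unit cell's atoms for the energy kernels."""

    M: np.ndarray                 # 3x3 lattice matrix, columns = vectors
    cart: np.ndarray              # (N, 3) Cartesian Å
    charges: np.ndarray           # (N,)
    elements: list[str]
    mol_index: np.ndarray         # (N,) which molecule image
    exclusions: list[tuple[int, int, float]]  # (i, j, scale) same-image pairs
    n_molecules: int
    overlap: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.cart)

    def volume(self) -> float:
        return float(abs(np.linalg.det(self.M)))


def _exclusion_pairs(molecule: Molecule, scale_14: float) -> list[tuple[int, int, float]]:
    """Intramolecular (i, j, scale): 0 at 1-2/1-3 range, ``scale_14`` at 1-4."""
    n = molecule.n_atoms
    adj = [set() for _ in range(n)]
    for i, j in molecule.bonds:
        adj[i].add(j)
        adj[j].add(i)
    out = []
    for i in range(n):
        # breadth-first to depth 3
        dist = {i: 0}
        frontier = [i]
        for d in (1, 2, 3):
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in dist:
                        dist[b] = d
                        nxt.append(b)
            frontier = nxt
        for j, d in dist.items():
            if j > i and d in (1, 2, 3):
                out.append((i, j, 0.0 if d < 3 else scale_14))
    return out


def cell_atoms(structure: CrystalStructure, ff: ForceField,
               hard_core: float = 0.6) -> CellAtoms:
    """Expand a structure into the flat per-cell atom list."""
    frac, overlap = expand_asymmetric_unit(structure, hard_core=hard_core)
    Z, n, _ = frac.shape
    M = structure.cell.matrix()
    cart = np.einsum("ij,znj->zni", M, frac).reshape(Z * n, 3)
    mol = structure.molecule
    base_excl = _exclusion_pairs(mol, ff.scale_14)
    exclusions = [(i + z * n, j + z * n, s)
                  for z in range(Z) for (i, j, s) in base_excl]
    return CellAtoms(
        M=M,
        cart=cart,
        charges=np.tile(mol.charges, Z),
        elements=list(mol.elements) * Z,
        mol_index=np.repeat(np.arange(Z), n),
        exclusions=exclusions,
        n_molecules=Z,
        overlap=overlap,
    )


def replicate_cell(atoms: CellAtoms, reps: tuple[int, int, int]) -> CellAtoms:
    """Supercell re-description (used by extensivity checks)."""
    na, nb, nc = reps
    shifts = [np.array(s, float) for s in itertools.product(range(na), range(nb), range(nc))]
    n = atoms.n_atoms
    carts, excl, mols = [], [], []
    for m, s in enumerate(shifts):
        carts.append(atoms.cart + atoms.M @ s)
        excl.extend([(i + m * n, j + m * n, sc) for i, j, sc in atoms.exclusions])
        mols.append(atoms.mol_index + m * atoms.n_molecules)
    M = atoms.M @ np.diag([na, nb, nc])
    return CellAtoms(
        M=M,
        cart=np.vstack(carts),
        charges=np.tile(atoms.charges, len(shifts)),
        elements=atoms.elements * len(shifts),
        mol_index=np.concatenate(mols),
        exclusions=excl,
        n_molecules=atoms.n_molecules * len(shifts),
        overlap=atoms.overlap,
    )


# ---------------------------------------------------------------------------
# real-space lattice sums

_R_CAP = 1e-3  # distances capped below this to keep energies finite


def _image_shifts(M: np.ndarray, cutoff: float) -> np.ndarray:
    """Half-set of lattice translations with perpendicular reach <= cutoff."""
    V = abs(np.linalg.det(M))
    a, b, c = M.T
    widths = np.array([
        V / np.linalg.norm(np.cross(b, c)),
        V / np.linalg.norm(np.cross(c, a)),
        V / np.linalg.norm(np.cross(a, b)),
    ])
    nmax = np.ceil(cutoff / widths).astype(int)
    out = []
    for n1 in range(-nmax[0], nmax[0] + 1):
        for n2 in range(-nmax[1], nmax[1] + 1):
            for n3 in range(-nmax[2], nmax[2] + 1):
                if (n1, n2, n3) > (0, 0, 0):
                    out.append((n1, n2, n3))
    return np.array(out, dtype=float) if out else np.zeros((0, 3))


def _pair_tables(atoms: CellAtoms, ff: ForceField):
    els = sorted(set(atoms.elements))
    t_index = {e: i for i, e in enumerate(els)}
    nt = len(els)
    eps = np.zeros((nt, nt))
    sig = np.ones((nt, nt))
    c6 = np.zeros((nt, nt))
    damp = np.zeros((nt, nt))
    for e1 in els:
        for e2 in els:
            p = ff.pair(e1, e2)
            i, j = t_index[e1], t_index[e2]
            eps[i, j], sig[i, j], c6[i, j], damp[i, j] = p.epsilon, p.sigma, p.c6, p.damping
    types = np.array([t_index[e] for e in atoms.elements])
    return types, eps, sig, c6, damp


def _tt_damping(x: np.ndarray) -> np.ndarray:
    """Tang-Toennies f6 damping: 1 - exp(-x) * sum_{k<=6} x^k / k!."""
    s = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(1, 7):
        term = term * x / k
        s = s + term
    return 1.0 - np.exp(-x) * s


#: switching turns on at this fraction of the cutoff
_SWITCH_ON = 0.85


def _switch(r, r_on, r_off, deriv=False):
    """XPLOR switching: C1-smooth taper of the pair term to zero at cutoff."""
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    denom = (off2 - on2) ** 3
    s = np.where(r <= r_on, 1.0,
                 np.where(r >= r_off, 0.0,
                          (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / denom))
    if not deriv:
        return s
    ds = np.where((r > r_on) & (r < r_off),
                  12.0 * r * (off2 - r2) * (on2 - r2) / denom, 0.0)
    return s, ds


def _pair_energy(r, eps, sig, c6, damp, r_off=None, deriv=False):
    r = np.maximum(r, _R_CAP)
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    has_c6 = np.any(c6 > 0)
    if has_c6:
        x = damp * r
        f6 = _tt_damping(x)
        e = e - f6 * c6 / r ** 6
    if not deriv:
        if r_off is not None:
            e = e * _switch(r, _SWITCH_ON * r_off, r_off)
        return e
    de = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    if has_c6:
        x = damp * r
        f6 = _tt_damping(x)
        # d/dr [ -f6(br) c6 r^-6 ]
        df6 = np.exp(-x) * x ** 6 / 720.0 * damp
        de = de + 6.0 * f6 * c6 / r ** 7 - df6 * c6 / r ** 6
    if r_off is not None:
        s, ds = _switch(r, _SWITCH_ON * r_off, r_off, deriv=True)
        de = de * s + e * ds
        e = e * s
    return e, de


def repulsion_dispersion(atoms: CellAtoms, ff: ForceField,
                         forces: np.ndarray | None = None) -> float:
    """Repulsion-dispersion energy of one unit cell (kJ/mol).

    If ``forces`` (N, 3) is given, the analytic -dE/dr contribution is
    accumulated into it.
    """
    types, eps, sig, c6, damp = _pair_tables(atoms, ff)
    cart = atoms.cart
    N = atoms.n_atoms
    cutoff = ff.real_cutoff
    want_f = forces is not None

    ii, jj = np.triu_indices(N, k=1)
    e_t, s_t, c_t, d_t = eps[types[ii], types[jj]], sig[types[ii], types[jj]], \
        c6[types[ii], types[jj]], damp[types[ii], types[jj]]
    scale0 = np.ones(len(ii))
    if atoms.exclusions:
        emap = {(i, j): s for i, j, s in atoms.exclusions}
        for idx, (i, j) in enumerate(zip(ii, jj)):
            s = emap.get((int(i), int(j)))
            if s is not None:
                scale0[idx] = s

    total = 0.0
    # home cell, each unordered pair once, exclusion scaling applied
    d0 = cart[jj] - cart[ii]
    r0 = np.linalg.norm(d0, axis=1)
    mask = r0 <= cutoff
    if np.any(mask):
        if want_f:
            e, de = _pair_energy(r0[mask], e_t[mask], s_t[mask], c_t[mask],
                                 d_t[mask], r_off=cutoff, deriv=True)
            total += float(np.sum(scale0[mask] * e))
            fpair = (scale0[mask] * de / np.maximum(r0[mask], _R_CAP))[:, None] * d0[mask]
            np.add.at(forces, ii[mask], fpair)
            np.add.at(forces, jj[mask], -fpair)
        else:
            e = _pair_energy(r0[mask], e_t[mask], s_t[mask], c_t[mask], d_t[mask],
                             r_off=cutoff)
            total += float(np.sum(scale0[mask] * e))

    # periodic images: half-set of shifts, all ordered pairs (incl. i == j)
    shifts = _image_shifts(atoms.M, cutoff)
    if len(shifts):
        ep = eps[types[:, None], types[None, :]]
        sp = sig[types[:, None], types[None, :]]
        cp = c6[types[:, None], types[None, :]]
        dp = damp[types[:, None], types[None, :]]
        offs = shifts @ atoms.M.T                               # (S, 3)
        d = (cart[None, None, :, :] - cart[None, :, None, :]
             + offs[:, None, None, :])                          # (S, N, N, 3)
        r = np.linalg.norm(d, axis=-1)
        m = r <= cutoff
        if np.any(m):
            s_idx, i_idx, j_idx = np.nonzero(m)
            if want_f:
                e, de = _pair_energy(r[m], ep[i_idx, j_idx], sp[i_idx, j_idx],
                                     cp[i_idx, j_idx], dp[i_idx, j_idx],
                                     r_off=cutoff, deriv=True)
                total += float(np.sum(e))
                fvec = (de / np.maximum(r[m], _R_CAP))[:, None] * d[m]
                np.add.at(forces, i_idx, fvec)
                np.add.at(forces, j_idx, -fvec)
            else:
                total += float(np.sum(_pair_energy(
                    r[m], ep[i_idx, j_idx], sp[i_idx, j_idx],
                    cp[i_idx, j_idx], dp[i_idx, j_idx], r_off=cutoff)))
    return total


# ---------------------------------------------------------------------------
# Ewald summation


def _ewald_params(atoms: CellAtoms, ff: ForceField, alpha: float | None):
    acc = ff.ewald_accuracy
    s = math.sqrt(max(-math.log(acc / K_E), 1.0))
    if alpha is None:
        alpha = ff.ewald_alpha
    if alpha is None:
        V = atoms.volume()
        alpha = float(np.clip((atoms.n_atoms * math.pi ** 3 / V ** 2) ** (1 / 6),
                              0.25, 1.2))
    r_cut = s / alpha
    k_cut = 2.0 * alpha * s
    return alpha, r_cut, k_cut


def coulomb_ewald(atoms: CellAtoms, ff: ForceField,
                  alpha: float | None = None,
                  forces: np.ndarray | None = None) -> float:
    """Coulomb energy of one unit cell by Ewald summation (kJ/mol).

    The splitting parameter ``alpha`` (Å^-1) may be overridden; real and
    reciprocal cutoffs are derived from it and the accuracy target, so
    the result is alpha-independent to within that target.
    """
    q = atoms.charges
    if not np.any(q):
        return 0.0
    if abs(q.sum()) > 1e-8:
        raise EwaldNeutralityError(
            f"unit cell has net charge {q.sum():g}; Ewald requires neutrality")
    alpha, r_cut, k_cut = _ewald_params(atoms, ff, alpha)
    cart = atoms.cart
    N = atoms.n_atoms
    want_f = forces is not None

    qq_half = q[:, None] * q[None, :]
    total = 0.0
    # home cell pairs (i < j)
    ii, jj = np.triu_indices(N, k=1)
    d0 = cart[jj] - cart[ii]
    r0 = np.linalg.norm(d0, axis=1)
    m = r0 <= r_cut
    if np.any(m):
        rm = r0[m]
        qq = q[ii[m]] * q[jj[m]]
        total += float(np.sum(K_E * qq * erfc(alpha * rm) / rm))
        if want_f:
            de = -K_E * qq * (erfc(alpha * rm) / rm ** 2
                              + 2.0 * alpha / math.sqrt(math.pi)
                              * np.exp(-(alpha * rm) ** 2) / rm)
            fvec = (de / rm)[:, None] * d0[m]
            np.add.at(forces, ii[m], fvec)
            np.add.at(forces, jj[m], -fvec)

    # periodic images
    shifts = _image_shifts(atoms.M, r_cut)
    if len(shifts):
        offs = shifts @ atoms.M.T
        d = (cart[None, None, :, :] - cart[None, :, None, :]
             + offs[:, None, None, :])
        r = np.linalg.norm(d, axis=-1)
        m = r <= r_cut
        if np.any(m):
            _, i_idx, j_idx = np.nonzero(m)
            rm = r[m]
            qq = q[i_idx] * q[j_idx]
            total += float(np.sum(K_E * qq * erfc(alpha * rm) / rm))
            if want_f:
                de = -K_E * qq * (erfc(alpha * rm) / rm ** 2
                                  + 2.0 * alpha / math.sqrt(math.pi)
                                  * np.exp(-(alpha * rm) ** 2) / rm)
                fvec = (de / rm)[:, None] * d[m]
                np.add.at(forces, i_idx, fvec)
                np.add.at(forces, j_idx, -fvec)

    # reciprocal part
    V = atoms.volume()
    B = 2.0 * math.pi * np.linalg.inv(atoms.M).T
    hmax = np.ceil(k_cut / np.linalg.norm(B, axis=0)).astype(int) + 1
    hs = []
    for h1 in range(-hmax[0], hmax[0] + 1):
        for h2 in range(-hmax[1], hmax[1] + 1):
            for h3 in range(-hmax[2], hmax[2] + 1):
                if (h1, h2, h3) > (0, 0, 0):
                    hs.append((h1, h2, h3))
    hs = np.array(hs, dtype=float)
    kvecs = hs @ B.T
    k2 = np.einsum("ij,ij->i", kvecs, kvecs)
    keep = (k2 > 0) & (k2 <= k_cut ** 2)
    kvecs, k2 = kvecs[keep], k2[keep]
    if len(kvecs):
        phase = cart @ kvecs.T                      # (N, K)
        ex = np.exp(1j * phase)
        S = q @ ex                                  # (K,)
        g = np.exp(-k2 / (4.0 * alpha ** 2)) / k2
        # half-space of k vectors -> factor 2
        total += float(K_E * (2.0 * math.pi / V) * np.sum(g * np.abs(S) ** 2) * 2.0)
        if want_f:
            # F_i = -(4 pi K_E q_i / V) sum_k g(k) k Im[e^{-i k r_i} S(k)], x2 half-space
            im = np.imag(np.conj(ex) * S[None, :])  # (N, K)
            fk = -(4.0 * math.pi * K_E / V) * ((g[None, :] * im) @ kvecs) * q[:, None] * 2.0
            forces += fk

    # self term
    total -= K_E * alpha / math.sqrt(math.pi) * float(np.sum(q * q))

    # intramolecular exclusion corrections at direct (same-image) distances
    for i, j, scale in atoms.exclusions:
        if scale == 1.0:
            continue
        d = cart[j] - cart[i]
        r = max(float(np.linalg.norm(d)), _R_CAP)
        total -= (1.0 - scale) * K_E * q[i] * q[j] / r
        if want_f:
            de = (1.0 - scale) * K_E * q[i] * q[j] / r ** 2
            fvec = de * d / r
            forces[i] += fvec
            forces[j] -= fvec
    return total


def cell_forces(atoms: CellAtoms, ff: ForceField,
                alpha: float | None = None) -> np.ndarray:
    """Analytic Cartesian forces -dE/dr (kJ mol^-1 Å^-1) on every cell atom.

    Covers the nonbonded (repulsion-dispersion + Coulomb) cell energy;
    torsion terms act on internal coordinates and are handled by the
    minimizer's reduced-gradient projection.
    """
    f = np.zeros_like(atoms.cart)
    repulsion_dispersion(atoms, ff, forces=f)
    coulomb_ewald(atoms, ff, alpha=alpha, forces=f)
    return f


def torsion_energy(molecule: Molecule, torsion_angles: np.ndarray,
                   ff: ForceField) -> float:
    """Intramolecular torsion energy (kJ/mol per molecule)."""
    e = 0.0
    for t, phi in zip(molecule.torsions, np.asarray(torsion_angles, float)):
        term = ff.torsions.get(t.type)
        if term is None:
            continue
        e += 0.5 * term.barrier * (
            1.0 + math.cos(math.radians(term.periodicity * phi - term.phase)))
    return e


def lattice_energy(structure: CrystalStructure, ff: ForceField,
                   pressure: float = 0.0,
                   alpha: float | None = None) -> EnergyBreakdown:
    """Lattice energy per molecule, optionally with the pV enthalpy term.

    Structures whose expansion brings atoms inside the hard-core radius
    are still evaluated but flagged via ``overlap``.
    """
    if pressure < 0:
        raise ValueError("negative pressure is outside the supported regime")
    setting = get_setting(structure.space_group)
    atoms = cell_atoms(structure, ff)
    Z = setting.multiplicity
    e_rd = repulsion_dispersion(atoms, ff) / Z
    e_coul = coulomb_ewald(atoms, ff, alpha=alpha) / Z
    e_tors = torsion_energy(structure.molecule, structure.torsion_angles, ff)
    pv = 0.0
    if pressure > 0.0:
        v_mol = cell_volume(structure.cell) / Z
        pv = pressure * v_mol * GPA_A3_TO_KJ_MOL
    return EnergyBreakdown(
        repdisp=e_rd + ff.energy_offset,
        coulomb=e_coul,
        torsion=e_tors,
        pv=pv,
        overlap=atoms.overlap,
    )


def enthalpy(structure: CrystalStructure, ff: ForceField, pressure: float) -> float:
    """H = E + p.V per molecule (kJ/mol); p in GPa, H(0) = E exactly."""
    return lattice_energy(structure, ff, pressure=pressure).total


def stress_tensor(structure: CrystalStructure, ff: ForceField,
                  strain_step: float = 1e-4) -> np.ndarray:
    """Symmetric stress tensor sigma = (1/V) dE/d(strain) in kJ mol^-1 Å^-3.

    Central finite differences over the six symmetric strain components;
    the molecule responds rigidly (fractional centroid fixed, orientation
    and conformation unchanged), matching the cell degrees of freedom the
    minimizer actually varies.
    """
    from .structures import UnitCell

    M0 = structure.cell.matrix()
    V0 = cell_volume(structure.cell)

    def energy_strained(eps_mat: np.ndarray) -> float:
        Ms = (np.eye(3) + eps_mat) @ M0
        # rebuild cell parameters from the strained lattice vectors
        a, b, c = Ms.T
        la, lb, lc = (float(np.linalg.norm(v)) for v in (a, b, c))
        al = math.degrees(math.acos(float(b @ c) / (lb * lc)))
        be = math.degrees(math.acos(float(a @ c) / (la * lc)))
        ga = math.degrees(math.acos(float(a @ b) / (la * lb)))
        s = structure.replace(cell=UnitCell(la, lb, lc, al, be, ga))
        bd = lattice_energy(s, ff)
        Z = get_setting(structure.space_group).multiplicity
        return bd.total * Z  # cell energy

    sigma = np.zeros((3, 3))
    for a in range(3):
        for b in range(a, 3):
            eps = np.zeros((3, 3))
            eps[a, b] = eps[b, a] = strain_step
            ep = energy_strained(eps)
            em = energy_strained(-eps)
            # d/d(eps_ab) with symmetric perturbation counts off-diagonals twice
            d = (ep - em) / (2.0 * strain_step)
            if a != b:
                d *= 0.5
            sigma[a, b] = sigma[b, a] = d / V0
    return sigma


# ---------------------------------------------------------------------------
# tailor-made force-field fitting


def _pack_params(ff: ForceField, fit_offset: bool):
    names, x0, lo, hi = [], [], [], []
    for key in sorted(ff.pairs):
        p = ff.pairs[key]
        names.append(f"epsilon[{key[0]}-{key[1]}]")
        x0.append(p.epsilon)
        lo.append(0.0)
        hi.append(np.inf)
        names.append(f"sigma[{key[0]}-{key[1]}]")
        x0.append(p.sigma)
        lo.append(0.05)
        hi.append(np.inf)
    for key in sorted(ff.torsions):
        names.append(f"barrier[{key}]")
        x0.append(ff.torsions[key].barrier)
        lo.append(0.0)
        hi.append(np.inf)
    if fit_offset:
        names.append("offset")
        x0.append(ff.energy_offset)
        lo.append(-np.inf)
        hi.append(np.inf)
    return names, np.array(x0), (np.array(lo), np.array(hi))


def _apply_params(ff: ForceField, x: np.ndarray, fit_offset: bool) -> ForceField:
    pairs = {}
    i = 0
    for key in sorted(ff.pairs):
        p = ff.pairs[key]
        pairs[key] = PairParams(float(x[i]), float(x[i + 1]), p.c6, p.damping)
        i += 2
    torsions = {}
    for key in sorted(ff.torsions):
        t = ff.torsions[key]
        torsions[key] = TorsionTerm(t.periodicity, float(x[i]), t.phase)
        i += 1
    offset = float(x[i]) if fit_offset else ff.energy_offset
    return ForceField(
        pairs=pairs, torsions=torsions,
        real_cutoff=ff.real_cutoff, ewald_accuracy=ff.ewald_accuracy,
        ewald_alpha=ff.ewald_alpha, scale_14=ff.scale_14,
        energy_offset=offset, provenance=dict(ff.provenance),
    )


def fit_force_field(reference: list, template: ForceField,
                    fit_offset: bool = False,
                    force_weight: float = 0.1) -> ForceField:
    """Fit pair and torsion parameters to reference energies (and forces).

    ``reference`` is a list of ``(structure, energy)`` or
    ``(structure, energy, forces)`` tuples; energies are kJ/mol per
    molecule, forces (when given) are per-cell-atom arrays weighted by
    ``force_weight``. Returns a new force field with fit provenance
    (residual RMS, reference hash); a rank-deficient Jacobian triggers a
    warning listing the unconstrained parameters.
    """
    names, x0, bounds = _pack_params(template, fit_offset)
    n_resid = sum(1 + (len(r) > 2) * 3 * len(cell_atoms(r[0], template).cart)
                  for r in reference)
    if n_resid < len(x0):
        raise ValueError(
            f"{n_resid} residuals cannot constrain {len(x0)} parameters")

    def residuals(x):
        ff = _apply_params(template, x, fit_offset)
        out = []
        for entry in reference:
            s, e_ref = entry[0], entry[1]
            out.append(lattice_energy(s, ff).total - e_ref)
            if len(entry) > 2 and entry[2] is not None:
                f_model = cell_forces(cell_atoms(s, ff), ff)
                out.extend(force_weight * (f_model - entry[2]).ravel())
        return np.array(out)

    res = least_squares(residuals, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    sv = np.linalg.svd(res.jac, compute_uv=False)
    degenerate = []
    if sv[0] > 0:
        _, _, vt = np.linalg.svd(res.jac)
        for k, s in enumerate(sv):
            if s < 1e-8 * sv[0]:
                worst = int(np.argmax(np.abs(vt[k])))
                degenerate.append(names[worst])
    if degenerate:
        warnings.warn(
            "rank-deficient fit; unconstrained parameters: " + ", ".join(degenerate))
    energies = np.array([r[1] for r in reference])
    ref_hash = hashlib.sha256(np.round(energies, 9).tobytes()).hexdigest()[:16]
    fitted = _apply_params(template, res.x, fit_offset)
    fitted.provenance = {
        "origin": "fitted",
        "residual_rms": float(np.sqrt(np.mean(residuals(res.x) ** 2))),
        "n_reference": len(reference),
        "reference_hash": ref_hash,
        "degenerate_parameters": degenerate,
    }
    return fitted


# ---------------------------------------------------------------------------
# force-field file I/O


def write_force_field(ff: ForceField, path) -> None:
    doc = {
        "pairs": {
            f"{k[0]}-{k[1]}": {"epsilon": p.epsilon, "sigma": p.sigma,
                               "c6": p.c6, "damping": p.damping}
            for k, p in sorted(ff.pairs.items())
        },
        "torsions": {
            k: {"periodicity": t.periodicity, "barrier": t.barrier, "phase": t.phase}
            for k, t in sorted(ff.torsions.items())
        },
        "real_cutoff": ff.real_cutoff,
        "ewald_accuracy": ff.ewald_accuracy,
        "ewald_alpha": ff.ewald_alpha,
        "scale_14": ff.scale_14,
        "energy_offset": ff.energy_offset,
        "provenance": ff.provenance,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_force_field(path) -> ForceField:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ForceField(
        pairs={tuple(k.split("-")): PairParams(**v) for k, v in doc["pairs"].items()},
        torsions={k: TorsionTerm(**v) for k, v in doc.get("torsions", {}).items()},
        real_cutoff=doc.get("real_cutoff", 10.0),
        ewald_accuracy=doc.get("ewald_accuracy", 1e-5),
        ewald_alpha=doc.get("ewald_alpha"),
        scale_14=doc.get("scale_14", 0.5),
        energy_offset=doc.get("energy_offset", 0.0),
        provenance=doc.get("provenance", {"origin": "file"}),
    )
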