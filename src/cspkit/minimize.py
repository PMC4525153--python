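"""Local lattice-energy/enthalpy minimization under symmetry constraints.

The objective is H = E + p·V per molecule, minimized over the reduced
coordinate vector: symmetry-free cell parameters, fractional centroid,
orientation quaternion and torsion angles. Space-group symmetry is a
hard constraint — only lattice-system-allowed cell deformations and the
asymmetric unit's degrees of freedom ever vary.

Convergence is reported against four simultaneous criteria (defaults
0.003 Å max atomic displacement between the final iterations, 0.001
kJ/mol per atom energy change, 1.7 kJ mol⁻¹ Å⁻¹ max atomic force and
0.0125 kbar cell-stress residual). Force and stress are evaluated on the
components realizable by the free degrees of freedom: in a rigid-fragment
model the raw atomic forces contain constraint components that cannot
relax, so the criteria are applied to the projected driving force and to
the stress projected onto the lattice system's allowed strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import KJ_MOL_A3_TO_KBAR
from .energy import EnergyBreakdown, ForceField, lattice_energy, \
    stress_tensor
from .structures import CrystalStructure, UnitCell
from .symmetry import get_setting, lattice_system_constraints

__all__ = [
    "ToleranceSet",
    "ConvergenceReport",
    "MinimizeResult",
    "minimize_lattice",
    "check_convergence",
    "projected_stress_residual",
]

_ANGLE_SCALE = 30.0   # degrees per optimizer unit
_FRAC_SCALE = 0.2     # fractional units per optimizer unit


@dataclass(frozen=True)
class ToleranceSet:
    """The four simultaneous convergence tolerances."""

    displacement: float = 0.003      # Å
    energy_per_atom: float = 0.001   # kJ/mol per atom
    force: float = 1.7               # kJ mol^-1 Å^-1
    stress: float = 0.0125           # kbar

    def __post_init__(self) -> None:
        if min(self.displacement, self.energy_per_atom, self.force, self.stress) <= 0:
            raise ValueError("all tolerances must be strictly positive")


@dataclass
class ConvergenceReport:
    """Per-criterion values and pass flags for one minimization."""

    converged: bool
    criteria: dict              # name -> (value, passed)
    iterations: int
    pressure: float
    message: str = ""

    def failed(self) -> list[str]:
        return [k for k, (_, ok) in self.criteria.items() if not ok]


@dataclass
class MinimizeResult:
    structure: CrystalStructure
    breakdown: EnergyBreakdown
    report: ConvergenceReport
    trajectory: list = field(default_factory=list, repr=False)


def check_convergence(trajectory_tail, tol: ToleranceSet,
                      max_force: float, stress_residual: float,
                      n_atoms: int) -> ConvergenceReport:
    """Evaluate the four criteria on the last two trajectory points.

    ``trajectory_tail`` is a sequence of ``(coords, energy)`` pairs
    (Cartesian Å, kJ/mol per molecule) of which the final two are used;
    ``max_force``/``stress_residual`` describe the final state.
    """
    if len(trajectory_tail) < 2:
        raise ValueError("need at least two iterations to check convergence")
    (c_prev, e_prev), (c_last, e_last) = trajectory_tail[-2], trajectory_tail[-1]
    disp = float(np.max(np.linalg.norm(np.asarray(c_last) - np.asarray(c_prev), axis=-1)))
    de_atom = abs(e_last - e_prev) / n_atoms
    criteria = {
        "displacement": (disp, disp <= tol.displacement),
        "energy_per_atom": (de_atom, de_atom <= tol.energy_per_atom),
        "force": (max_force, max_force <= tol.force),
        "stress": (stress_residual, stress_residual <= tol.stress),
    }
    return ConvergenceReport(
        converged=all(ok for _, ok in criteria.values()),
        criteria=criteria,
        iterations=len(trajectory_tail) - 1,
        pressure=float("nan"),
    )


# ---------------------------------------------------------------------------
# reduced coordinates

_CELL_BOUNDS = {"length": (2.0, 80.0), "angle": (45.0, 135.0)}


def _pack(structure: CrystalStructure, free_cell: tuple[str, ...],
          freeze_cell: bool, freeze_torsions: bool = False) -> np.ndarray:
    x = []
    if not freeze_cell:
        cell = structure.cell
        for name in free_cell:
            v = getattr(cell, name)
            x.append(v if name in "abc" else v / _ANGLE_SCALE)
    x.extend(structure.position / _FRAC_SCALE)
    x.extend(structure.orientation)
    if not freeze_torsions:
        x.extend(np.asarray(structure.torsion_angles) / _ANGLE_SCALE)
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray, template: CrystalStructure,
            free_cell: tuple[str, ...], freeze_cell: bool,
            freeze_torsions: bool = False) -> CrystalStructure:
    from .symmetry import apply_lattice_constraints
    setting = get_setting(template.space_group)
    i = 0
    if freeze_cell:
        cell = template.cell
    else:
        vals = {}
        for name in free_cell:
            v = x[i]
            vals[name] = v if name in "abc" else v * _ANGLE_SCALE
            i += 1
        full = apply_lattice_constraints(setting, vals)
        cell = UnitCell(**full)
    pos = (np.array(x[i:i + 3]) * _FRAC_SCALE) % 1.0
    i += 3
    q = np.array(x[i:i + 4])
    q = q / np.linalg.norm(q)
    i += 4
    if freeze_torsions:
        tors = np.array(template.torsion_angles)
    else:
        tors = np.array(x[i:]) * _ANGLE_SCALE
    return template.replace(cell=cell, position=pos, orientation=q,
                            torsion_angles=tors)


#: reject cells whose metric discriminant falls below this (near-degenerate)
_MIN_METRIC_DISC = 0.02


def _cell_barrier(x, template, free_cell, freeze_cell) -> float:
    """Smooth penalty outside the valid-cell region (0 inside).

    Gives the optimizer a restoring gradient instead of a flat cliff
    when a trial step produces a (near-)degenerate metric.
    """
    if freeze_cell or not free_cell:
        return 0.0
    from .symmetry import apply_lattice_constraints
    setting = get_setting(template.space_group)
    vals = {}
    for i, name in enumerate(free_cell):
        vals[name] = x[i] if name in "abc" else x[i] * _ANGLE_SCALE
    full = apply_lattice_constraints(setting, vals)
    pen = 0.0
    for name in ("a", "b", "c"):
        pen += max(0.0, 2.0 - full[name])
    ca, cb, cg = (math.cos(math.radians(full[k]))
                  for k in ("alpha", "beta", "gamma"))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    pen += max(0.0, _MIN_METRIC_DISC - disc) * 50.0
    return pen


def _position_jacobian(x, template, free_cell, freeze_cell,
                       freeze_torsions=False, h=1e-5):
    """d(cell Cartesian coords)/d(reduced coords) by central differences."""
    from .symmetry import expand_asymmetric_unit

    def coords(xv):
        s = _unpack(xv, template, free_cell, freeze_cell, freeze_torsions)
        frac, _ = expand_asymmetric_unit(s, hard_core=0.0)
        M = s.cell.matrix()
        return np.einsum("ij,znj->zni", M, frac).reshape(-1, 3)

    base = coords(x)
    J = np.zeros((base.size, len(x)))
    for k in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (coords(xp) - coords(xm)).ravel() / (2 * h)
    return J, base


_ALLOWED_STRAINS = {
    # 6-vector order: xx, yy, zz, yz, xz, xy
    "triclinic": [(0,), (1,), (2,), (3,), (4,), (5,)],
    "monoclinic": [(0,), (1,), (2,), (4,)],
    "orthorhombic": [(0,), (1,), (2,)],
    "tetragonal": [(0, 1), (2,)],
    "trigonal": [(0, 1), (2,)],
    "hexagonal": [(0, 1), (2,)],
    "cubic": [(0, 1, 2)],
}


def projected_stress_residual(structure: CrystalStructure, ff: ForceField,
                              pressure: float) -> float:
    """Max |component| (kbar) of (sigma + p·I) in the allowed strain space."""
    from .constants import GPA_A3_TO_KJ_MOL
    setting = get_setting(structure.space_group)
    sigma = stress_tensor(structure, ff)           # kJ/mol/Å^3
    p_internal = pressure * GPA_A3_TO_KJ_MOL       # GPa -> kJ/mol/Å^3
    resid = sigma + np.eye(3) * p_internal
    vec = np.array([resid[0, 0], resid[1, 1], resid[2, 2],
                    resid[1, 2], resid[0, 2], resid[0, 1]])
    allowed = _ALLOWED_STRAINS[setting.crystal_system]
    comps = [np.mean(vec[list(group)]) for group in allowed]
    return float(np.max(np.abs(comps)) * KJ_MOL_A3_TO_KBAR)


def _projected_max_force(x, template, free_cell, freeze_cell, objective,
                         freeze_torsions=False, g_step=1e-5):
    """Max per-atom norm of the driving force realizable by the free DOF.

    The reduced gradient g (finite differences of the objective) is
    mapped back to a Cartesian force field F = J (JᵀJ)⁻¹ g lying in the
    span of the achievable atomic displacements.
    """
    g = np.zeros(len(x))
    for k in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[k] += g_step
        xm[k] -= g_step
        g[k] = (objective(xp) - objective(xm)) / (2 * g_step)
    J, _ = _position_jacobian(x, template, free_cell, freeze_cell,
                              freeze_torsions)
    # guard the quaternion-norm null direction and any frozen DOF
    JtJ = J.T @ J
    F = J @ np.linalg.lstsq(JtJ, g, rcond=1e-10)[0]
    return float(np.max(np.linalg.norm(F.reshape(-1, 3), axis=1)))


def minimize_lattice(structure: CrystalStructure, ff: ForceField,
                     pressure: float = 0.0,
                     tol: ToleranceSet = ToleranceSet(),
                     max_iterations: int = 2000,
                     freeze_cell: bool = False,
                     freeze_torsions: bool = False,
                     keep_trajectory: bool = False) -> MinimizeResult:
    """Minimize H = E + p·V over the symmetry-allowed degrees of freedom.

    Success requires all four tolerance criteria simultaneously; hitting
    the iteration cap returns the best state flagged unconverged. The
    output structure always retains the input space group.
    """
    if pressure < 0:
        raise ValueError("negative pressure is outside the supported regime")
    setting = get_setting(structure.space_group)
    free_cell = () if freeze_cell else lattice_system_constraints(setting)
    Z = setting.multiplicity
    n_atoms = structure.molecule.n_atoms

    def objective(x):
        pen = _cell_barrier(x, structure, free_cell, freeze_cell)
        if pen > 0.0:
            return 1e4 * (1.0 + pen)
        s = _unpack(x, structure, free_cell, freeze_cell, freeze_torsions)
        try:
            return lattice_energy(s, ff, pressure=pressure).total
        except ValueError:
            return 1e8

    bounds = []
    for name in free_cell:
        if name in "abc":
            bounds.append(_CELL_BOUNDS["length"])
        else:
            lo, hi = _CELL_BOUNDS["angle"]
            bounds.append((lo / _ANGLE_SCALE, hi / _ANGLE_SCALE))
    bounds += [(None, None)] * 3                      # centroid
    bounds += [(-1.5, 1.5)] * 4                       # quaternion components
    if not freeze_torsions:
        bounds += [(None, None)] * len(structure.molecule.torsions)

    x0 = _pack(structure, free_cell, freeze_cell, freeze_torsions)
    trajectory = [x0.copy()]
    iterations = 0
    capped = False
    x = x0
    report = None

    for _round in range(4):
        budget = max_iterations - iterations
        if budget <= 0:
            capped = True
            break
        res = _scipy_minimize(
            objective, x, method="L-BFGS-B", bounds=bounds,
            callback=lambda xk: trajectory.append(xk.copy()),
            options={"maxiter": budget, "ftol": 1e-14, "gtol": 1e-9,
                     "eps": 1e-6},
        )
        iterations += res.nit
        x = res.x
        if _cell_barrier(x, structure, free_cell, freeze_cell) > 0.0:
            # walk back to the last valid iterate
            for xv in reversed(trajectory):
                if _cell_barrier(xv, structure, free_cell, freeze_cell) == 0.0:
                    x = xv
                    break
        report = _evaluate(x, trajectory, structure, free_cell, freeze_cell,
                           freeze_torsions, objective, ff, pressure, tol, Z,
                           n_atoms, iterations)
        if report.converged:
            break
        if not res.success and "ITERATIONS" in str(res.message).upper():
            capped = True
            break
    if report is None or (capped and report.converged):
        report = _evaluate(x, trajectory, structure, free_cell, freeze_cell,
                           freeze_torsions, objective, ff, pressure, tol, Z,
                           n_atoms, iterations)
    if capped:
        report.converged = False
        report.message = "iteration cap reached"
    elif not report.converged and not report.message:
        report.message = "criteria not met within restart budget"

    final = _unpack(x, structure, free_cell, freeze_cell, freeze_torsions)
    final = final.replace(label=structure.label)
    bd = lattice_energy(final, ff, pressure=pressure)
    bd.max_force = report.criteria["force"][0]
    bd.stress_residual = report.criteria["stress"][0]
    traj_out = []
    if keep_trajectory:
        for xv in trajectory:
            traj_out.append(_unpack(xv, structure, free_cell, freeze_cell,
                                    freeze_torsions))
    return MinimizeResult(structure=final, breakdown=bd, report=report,
                          trajectory=traj_out)


def _evaluate(x, trajectory, template, free_cell, freeze_cell,
              freeze_torsions, objective, ff, pressure, tol, Z, n_atoms,
              iterations) -> ConvergenceReport:
    s_last = _unpack(x, template, free_cell, freeze_cell, freeze_torsions)
    _, coords_last = _position_jacobian(x, template, free_cell, freeze_cell,
                                        freeze_torsions)
    e_last = objective(x)
    x_prev = None
    for xv in reversed(trajectory):
        if not np.allclose(xv, x):
            x_prev = xv
            break
    if x_prev is not None:
        _, coords_prev = _position_jacobian(x_prev, template, free_cell,
                                            freeze_cell, freeze_torsions)
        e_prev = objective(x_prev)
        disp = float(np.max(np.linalg.norm(coords_last - coords_prev, axis=1)))
        de_atom = abs(e_last - e_prev) / n_atoms
    else:
        disp, de_atom = 0.0, 0.0
    fmax = _projected_max_force(x, template, free_cell, freeze_cell,
                                objective, freeze_torsions)
    if freeze_cell:
        stress_resid = 0.0
    else:
        stress_resid = projected_stress_residual(s_last, ff, pressure)
    criteria = {
        "displacement": (disp, disp <= tol.displacement),
        "energy_per_atom": (de_atom, de_atom <= tol.energy_per_atom),
        "force": (fmax, fmax <= tol.force),
        "stress": (stress_resid, stress_resid <= tol.stress),
    }
    return ConvergenceReport(
        converged=all(ok for _, ok in criteria.values()),
        criteria=criteria,
        iterations=iterations,
        pressure=pressure,
    )
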