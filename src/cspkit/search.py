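"""Monte-Carlo parallel-tempering search with rediscovery-based stopping.

The sampler is generic over a *system* object providing::

    initial_state(rng)            -> state
    energy(state)                 -> float (kJ/mol)
    propose(state, rng)           -> (trial_state, move_label)
    quench(state)                 -> (minimized_state, energy)   [optional]
    key(state, energy)            -> hashable minimum identity   [optional]

Replicas run Metropolis sampling at a geometric temperature ladder and
attempt adjacent-pair configuration swaps (acceptance min(1, exp(Δβ·ΔE)))
at fixed intervals. Low-energy states are quenched to local minima and
entered into a rediscovery ledger; the search is declared converged when
each of the k lowest-lying distinct minima has been rediscovered
independently at least m times. Runs are reproducible from the seed.

The crystal-packing system couples this machinery to the lattice-energy
surrogate: moves are symmetry-preserving cell strains, rigid molecular
translations/rotations and single-torsion rotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import K_B
from .energy import ForceField, lattice_energy
from .minimize import minimize_lattice
from .structures import CrystalStructure, Molecule, UnitCell
from .symmetry import apply_lattice_constraints, get_setting, \
    lattice_system_constraints

__all__ = [
    "MoveSteps",
    "SearchState",
    "ConvergencePolicy",
    "ParallelTempering",
    "CrystalPackingSystem",
    "propose_move",
    "pt_run",
    "convergence_check",
    "geometric_ladder",
]


def geometric_ladder(t_min: float = 300.0, t_max: float = 3000.0,
                     n: int = 8) -> np.ndarray:
    """Geometric temperature ladder in K, strictly increasing."""
    return t_min * (t_max / t_min) ** (np.arange(n) / (n - 1))


@dataclass
class MoveSteps:
    """Step sizes for the four crystal move types."""

    cell: float = 0.3          # Å on lengths, scaled to degrees on angles
    translation: float = 0.3   # Å
    rotation: float = 25.0     # degrees
    torsion: float = 30.0      # degrees


@dataclass
class ConvergencePolicy:
    """Stop when the k best minima were each rediscovered >= m times."""

    k: int = 3
    m: int = 3


@dataclass
class SearchState:
    """Bookkeeping for one parallel-tempering run."""

    temperatures: np.ndarray
    replica_states: list
    replica_energies: list
    seed: int
    sweeps_done: int = 0
    acceptance: dict = field(default_factory=dict)       # move -> [acc, tried]
    swap_acceptance: list = field(default_factory=lambda: [0, 0])
    ledger: dict = field(default_factory=dict)           # key -> count
    minima: dict = field(default_factory=dict)           # key -> (energy, state)
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def acceptance_rates(self) -> dict:
        return {k: (a / t if t else 0.0) for k, (a, t) in self.acceptance.items()}


def convergence_check(state: SearchState,
                      policy: ConvergencePolicy) -> tuple[bool, dict]:
    """Rediscovery-count stopping rule.

    Converged when each of the ``policy.k`` lowest-energy distinct minima
    in the ledger has been reached independently at least ``policy.m``
    times; the report maps each of those minima to its count.
    """
    if not state.ledger:
        return False, {}
    ranked = sorted(state.minima, key=lambda k: state.minima[k][0])
    best = ranked[:policy.k]
    report = {k: state.ledger[k] for k in best}
    ok = len(best) >= policy.k and all(state.ledger[k] >= policy.m for k in best)
    return ok, report


class ParallelTempering:
    """Generic replica-exchange Metropolis sampler."""

    def __init__(self, system, temperatures=None, seed: int = 0,
                 swap_interval: int = 5,
                 quench_threshold: float = 0.3,
                 policy: ConvergencePolicy | None = None):
        self.system = system
        self.temperatures = np.asarray(
            geometric_ladder() if temperatures is None else temperatures, float)
        self.seed = seed
        self.swap_interval = swap_interval
        self.quench_threshold = quench_threshold
        self.policy = policy or ConvergencePolicy()
        self.rng = np.random.default_rng(seed)
        states = [system.initial_state(self.rng) for _ in self.temperatures]
        self.state = SearchState(
            temperatures=self.temperatures,
            replica_states=states,
            replica_energies=[system.energy(s) for s in states],
            seed=seed,
        )
        self.visits = [dict() for _ in self.temperatures]
        self._energy_window: list[float] = []

    # -- single components ---------------------------------------------------

    def metropolis_step(self, r: int) -> None:
        st = self.state
        beta = 1.0 / (K_B * self.temperatures[r])
        trial, label = self.system.propose(st.replica_states[r], self.rng)
        e_old = st.replica_energies[r]
        e_new = self.system.energy(trial)
        acc = st.acceptance.setdefault(label, [0, 0])
        acc[1] += 1
        if not math.isfinite(e_new):
            st.events.append(("reset", r, st.sweeps_done))
            st.replica_states[r] = self.system.initial_state(self.rng)
            st.replica_energies[r] = self.system.energy(st.replica_states[r])
            return
        if e_new <= e_old or self.rng.random() < math.exp(-beta * (e_new - e_old)):
            st.replica_states[r] = trial
            st.replica_energies[r] = e_new
            acc[0] += 1
            self._maybe_quench(r, e_new)

    def swap_step(self) -> None:
        st = self.state
        for r in range(len(self.temperatures) - 1):
            b1 = 1.0 / (K_B * self.temperatures[r])
            b2 = 1.0 / (K_B * self.temperatures[r + 1])
            d = (b1 - b2) * (st.replica_energies[r] - st.replica_energies[r + 1])
            st.swap_acceptance[1] += 1
            if d >= 0 or self.rng.random() < math.exp(d):
                st.swap_acceptance[0] += 1
                st.replica_states[r], st.replica_states[r + 1] = \
                    st.replica_states[r + 1], st.replica_states[r]
                st.replica_energies[r], st.replica_energies[r + 1] = \
                    st.replica_energies[r + 1], st.replica_energies[r]
                st.events.append(("swap", r, st.sweeps_done))

    def _maybe_quench(self, r: int, energy: float) -> None:
        if not hasattr(self.system, "quench"):
            return
        self._energy_window.append(energy)
        if len(self._energy_window) > 500:
            self._energy_window.pop(0)
        cut = np.quantile(self._energy_window, self.quench_threshold)
        if energy > cut:
            return
        qstate, qe = self.system.quench(self.state.replica_states[r])
        key = self.system.key(qstate, qe)
        st = self.state
        st.ledger[key] = st.ledger.get(key, 0) + 1
        if key not in st.minima or qe < st.minima[key][0]:
            st.minima[key] = (qe, qstate)
        st.events.append(("quench", key, st.sweeps_done))

    # -- driver --------------------------------------------------------------

    def run(self, n_sweeps: int, check_interval: int = 50,
            stop_when_converged: bool = True, track_visits: bool = False,
            visit_stride: int = 1):
        """Drive the ladder for ``n_sweeps`` sweeps.

        With ``track_visits`` the per-replica state occupancy is tallied
        every ``visit_stride``-th sweep; thinning reduces the Metropolis
        chain's autocorrelation so the tallies behave like independent
        draws in statistical checks.
        """
        st = self.state
        n_rep = len(self.temperatures)
        for sweep in range(n_sweeps):
            record = track_visits and (sweep % visit_stride == 0)
            for r in range(n_rep):
                self.metropolis_step(r)
                if record:
                    key = self.system.key(st.replica_states[r],
                                          st.replica_energies[r])
                    v = self.visits[r]
                    v[key] = v.get(key, 0) + 1
            st.sweeps_done += 1
            if st.sweeps_done % self.swap_interval == 0:
                self.swap_step()
            if (stop_when_converged and st.sweeps_done % check_interval == 0
                    and convergence_check(st, self.policy)[0]):
                break
        return st


# ---------------------------------------------------------------------------
# the crystal-packing system


def propose_move(structure: CrystalStructure, move_type: str,
                 steps: MoveSteps, rng: np.random.Generator) -> CrystalStructure:
    """One symmetry-preserving trial move.

    Cell moves perturb only the lattice system's free parameters, so the
    space-group constraints are preserved exactly by construction.
    """
    if move_type == "cell":
        setting = get_setting(structure.space_group)
        free = lattice_system_constraints(setting)
        vals = {}
        cell = structure.cell
        for name in free:
            v = getattr(cell, name)
            if name in "abc":
                vals[name] = max(2.0, v + rng.normal(0.0, steps.cell))
            else:
                vals[name] = float(np.clip(v + rng.normal(0.0, 10 * steps.cell),
                                           60.0, 140.0))
        full = apply_lattice_constraints(setting, vals)
        return structure.replace(cell=UnitCell(**full))
    if move_type == "translation":
        M = structure.cell.matrix()
        shift_cart = rng.normal(0.0, steps.translation, 3)
        shift_frac = np.linalg.solve(M, shift_cart)
        return structure.replace(position=(structure.position + shift_frac) % 1.0)
    if move_type == "rotation":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.normal(0.0, steps.rotation))
        dq = Rotation.from_rotvec(axis * angle)
        q0 = Rotation.from_quat(structure.orientation, scalar_first=True)
        q = (dq * q0).as_quat(scalar_first=True)
        return structure.replace(orientation=q / np.linalg.norm(q))
    if move_type == "torsion":
        n = len(structure.molecule.torsions)
        if n == 0:
            raise ValueError("torsion move unavailable: molecule is rigid")
        i = int(rng.integers(n))
        tors = np.array(structure.torsion_angles, float)
        tors[i] = (tors[i] + rng.normal(0.0, steps.torsion)) % 360.0
        return structure.replace(torsion_angles=tors)
    raise ValueError(f"unknown move type {move_type!r}")


class CrystalPackingSystem:
    """Couples the PT sampler to the lattice-energy surrogate."""

    def __init__(self, molecule: Molecule, space_group: int | str,
                 ff: ForceField, steps: MoveSteps | None = None,
                 quench_max_iter: int = 300,
                 energy_tol: float = 0.1, fingerprint_tol: float = 0.1):
        self.molecule = molecule
        self.space_group = space_group
        self.ff = ff
        self.steps = steps or MoveSteps()
        self.quench_max_iter = quench_max_iter
        self.energy_tol = energy_tol
        self.fingerprint_tol = fingerprint_tol
        self.setting = get_setting(space_group)
        self._moves = ["cell", "translation", "rotation"]
        if molecule.torsions:
            self._moves.append("torsion")
        span = float(np.max(np.ptp(molecule.coords, axis=0))) + 4.0
        self._span = span

    def initial_state(self, rng) -> CrystalStructure:
        free = lattice_system_constraints(self.setting)
        z = self.setting.multiplicity
        base = self._span * z ** (1 / 3)
        vals = {}
        for name in free:
            if name in "abc":
                vals[name] = base * rng.uniform(0.9, 1.4)
            else:
                vals[name] = rng.uniform(80.0, 110.0)
        cell = UnitCell(**apply_lattice_constraints(self.setting, vals))
        q = Rotation.random(rng=rng).as_quat(scalar_first=True)
        tors = rng.uniform(0.0, 360.0, len(self.molecule.torsions))
        return CrystalStructure(cell=cell, space_group=self.space_group,
                                molecule=self.molecule,
                                position=rng.uniform(0, 1, 3), orientation=q,
                                torsion_angles=tors)

    def energy(self, state: CrystalStructure) -> float:
        try:
            bd = lattice_energy(state, self.ff)
        except ValueError:
            return float("inf")
        return bd.total

    def propose(self, state, rng):
        move = self._moves[int(rng.integers(len(self._moves)))]
        return propose_move(state, move, self.steps, rng), move

    def quench(self, state):
        res = minimize_lattice(state, self.ff,
                               max_iterations=self.quench_max_iter)
        return res.structure, res.breakdown.total

    def key(self, state, energy):
        from .landscape import structure_fingerprint
        fp = structure_fingerprint(state)
        return (round(energy / self.energy_tol),
                tuple(np.round(fp / self.fingerprint_tol).astype(int)[:8]))


def pt_run(molecule: Molecule, space_group: int | str, ff: ForceField,
           config: dict | None = None) -> tuple[list, SearchState]:
    """Parallel-tempering packing search in one space group.

    ``config`` keys (all optional): temperatures, seed, n_sweeps,
    swap_interval, steps (MoveSteps), policy (ConvergencePolicy),
    quench_threshold, keep (number of minima returned). Returns the
    deduplicated quenched minima as ``(structure, energy)`` pairs sorted
    by energy, plus the final :class:`SearchState`.
    """
    cfg = config or {}
    system = CrystalPackingSystem(molecule, space_group, ff,
                                  steps=cfg.get("steps"))
    pt = ParallelTempering(
        system,
        temperatures=cfg.get("temperatures"),
        seed=cfg.get("seed", 0),
        swap_interval=cfg.get("swap_interval", 5),
        quench_threshold=cfg.get("quench_threshold", 0.3),
        policy=cfg.get("policy"),
    )
    state = pt.run(cfg.get("n_sweeps", 200),
                   check_interval=cfg.get("check_interval", 50))
    keep = cfg.get("keep", 20)
    found = sorted(state.minima.values(), key=lambda t: t[0])[:keep]
    return [(s, e) for e, s in found], state
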