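# cspkit

Desk-scale crystal structure prediction (CSP) and polymorph ranking for
flexible organic molecules.

Many drug-like molecules crystallize in several polymorphs with
different stability, density and solubility, and the thermodynamically
stable form may not be the one found first in the lab. `cspkit`
implements the computational side of a rational polymorph screen as a
reusable pipeline:

1. **Packing search** — parallel-tempering Monte Carlo over
   symmetry-constrained packings (cell, molecular position, orientation,
   torsions) in any of the 230 space groups with one molecule per
   asymmetric unit, with a rediscovery-count convergence rule.
2. **Energy ranking** — a classical lattice-energy model (Lennard-Jones
   / damped-dispersion + Ewald electrostatics + cosine torsions), with a
   *tailor-made* twist: the pair and torsion parameters are fitted by
   least squares to reference energies generated for the molecule under
   study.
3. **Landscape analytics** — deduplication of minima, clustering of
   conformational variants into packing families (named after their
   lowest-energy member), and the energy–density diagram with relative
   lattice energies calibrated so their mean is zero.
4. **Pressure re-ranking** — each structure is re-minimized on a
   hydrostatic-pressure grid (0.0–1.0 GPa in 0.2 GPa steps by default)
   with the enthalpy H = E + p·V as the ranking quantity; crossings of
   ΔH(p) against a reference flag polymorphs that become more stable
   under pressure — candidates for high-pressure crystallization.
5. **Configurational disorder** — a Boltzmann-population model
   F = −RT·ln Σ gᵢ·exp(−Eᵢ/RT) over the thermally accessible molecular
   conformations in a host lattice, quantifying how disorder can make a
   family with many accessible conformations beat an energetically
   close but conformationally rigid competitor.

Local minimization enforces the four-criterion convergence contract
(0.003 Å atomic displacement, 0.001 kJ/mol per atom energy change,
1.7 kJ mol⁻¹ Å⁻¹ atomic force, 0.0125 kbar cell stress — all
simultaneously). The intended users are method developers and students
who want a fully testable CSP pipeline whose every stage is validated
against exactly solvable systems; the classical energy model is a
surrogate for the dispersion-corrected DFT engines used in production
CSP, so absolute energies are not chemically predictive (see
`docs/methods.md`).

## Worked example

Screen a flexible toy molecule (2 rotatable torsions) in P2₁/c, rank
the minima, and scan the leading structures under pressure:

```python
from cspkit.synthetic import make_toy_molecule, default_force_field
from cspkit.search import pt_run
from cspkit.landscape import (deduplicate, cluster_families,
                              build_landscape, pressure_scan)

mol = make_toy_molecule(2, seed=0, charge_scale=0.0)
ff = default_force_field()
found, state = pt_run(mol, 14, ff, {"seed": 3, "n_sweeps": 30, "keep": 6,
                                    "temperatures": [400.0, 1200.0],
                                    "quench_threshold": 0.2})
structures = [s.replace(label=f"m{i+1}") for i, (s, e) in enumerate(found)]
energies = [e for _, e in found]
kept, _ = deduplicate(structures, energies)
reps = [structures[i] for i in kept]
rep_e = [energies[i] for i in kept]
families = cluster_families(reps, rep_e, [s.label for s in reps])
print(build_landscape(reps, rep_e, families=families).to_string(index=False))
```

```
label  rank  rel_energy  density family space_group     energy
   m1     1  -15.909155 0.953348     m1  P 1 21/c 1 -26.083141
   m2     2   -9.601876 0.475996     m2  P 1 21/c 1 -19.775861
   m3     3    2.106577 0.370002     m3  P 1 21/c 1  -8.067409
   m4     4    7.794614 0.068283     m4  P 1 21/c 1  -2.379371
   m5     5    7.804920 0.067963     m4  P 1 21/c 1  -2.369065
   m6     6    7.804920 0.065655     m4  P 1 21/c 1  -2.369065
```

Each row is one distinct local minimum: `rel_energy` is the lattice
energy in kJ/mol per molecule relative to the mean of the kept set (the
calibration makes the column average exactly zero), `density` is in
g/cm³, and `family` groups conformational variants of one packing under
the label of its most stable member (here m5 and m6 are conformational
variants of the m4 packing). The most stable, densest packing m1 leads
the landscape — the energy–density correlation typical of these
diagrams.

The disorder model, on a host with two degenerate accessible
conformations at E = −10 kJ/mol and T = 295 K:

```python
from cspkit.disorder import Configuration, config_free_energy
m = config_free_energy([Configuration("a", -10.0),
                        Configuration("b", -10.0)], 295.0)
print(round(m.free_energy, 5))   # -11.70013  ==  E - RT ln 2
```

The configurational entropy lowers the free energy by RT·ln 2 =
1.70 kJ/mol — enough to flip the ranking of two polymorphs a few
kJ/mol apart, which is the mechanism that decides which member of a
disordered family is observed experimentally.

A command-line interface mirrors the library (`cspkit screen`, `rank`,
`pressure-scan`, `crossings`, `compare`, `fixtures`); run
`cspkit --help` for details.

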