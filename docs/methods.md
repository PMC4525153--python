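# Methods

`cspkit` implements a desk-scale crystal structure prediction (CSP)
pipeline for flexible organic molecules: space-group-constrained packing
generation by parallel-tempering Monte Carlo, lattice-energy ranking with
a tailor-made classical force field, energy–density landscape
construction, pressure-dependent enthalpy re-ranking, and a
configurational-disorder free-energy model. This note documents the
models, the defaults and their rationale, the numerical choices, and what
the synthetic test systems do and do not establish.

## Data model and conventions

A crystal is described by a Z′ = 1 asymmetric unit: one molecule placed
by a fractional centroid in [0, 1)³, a unit quaternion orientation, and
one angle per rotatable torsion. Bond lengths and angles are held rigid;
torsions are the only internal degrees of freedom, which is the standard
rigid-fragment approximation for packing searches of chain-flexible
molecules. The crystallographic Cartesian frame puts **a** along x and
**b** in the xy-plane; torsion angles follow the IUPAC sign convention
(frozen by a fixture test). Energies are kJ/mol per molecule, distances
Å, pressures GPa; the single conversion 1 GPa·Å³ = 0.602214076 kJ/mol is
applied centrally.

## Symmetry

The operator tables for the 230 space groups (one canonical setting per
group: unique axis b, origin choice 2, hexagonal axes for rhombohedral
groups) are taken from gemmi's crystallographic tables at run time.
Group-theoretic validation — closure, identity, inverses modulo lattice
translations, and multiplicity = operator count — is performed by this
package over all 230 settings in about a second. Translation components
are checked against the n/12 lattice (the set {0, 1/4, 1/3, 1/2, 2/3,
3/4} often quoted omits the 1/6 and 5/6 translations of hexagonal screw
axes). Molecules always occupy the general position; special positions
and Z′ > 1 are out of scope. Cell parameters are constrained exactly to
the lattice system (triclinic 6 free parameters, monoclinic 4,
orthorhombic 3, tetragonal/trigonal/hexagonal 2, cubic 1); every cell
move and every minimization step works in this reduced parameter space,
so symmetry can never be broken by the search.

## Lattice-energy surrogate

The energy model is a classical surrogate with three components:

* **Repulsion–dispersion**: Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶] per
  element pair (Lorentz–Berthelot combination for missing cross terms),
  optionally augmented by a Tang–Toennies-damped −f₆(br)·C₆/r⁶ term.
  Pair interactions are tapered to zero by an XPLOR switching function
  between 0.85·r_cut and r_cut (default r_cut 10 Å) so the lattice sum
  is C¹-smooth — necessary because the minimizer differentiates the
  energy numerically.
* **Coulomb**: point charges summed by Ewald summation. The splitting
  parameter α defaults to (Nπ³/V²)^(1/6) (clamped to [0.25, 1.2] Å⁻¹);
  real and reciprocal cutoffs are derived from α and the accuracy
  target (default 1e-5 kJ/mol), so the total is α-independent to within
  that target — asserted in tests against a direct-space Evjen sum over
  expanding neutral shells, an oracle implemented independently of any
  Ewald machinery. Non-neutral cells are refused. Intramolecular pairs
  are excluded at 1–2/1–3 range and scaled by 0.5 at 1–4 range
  (configurable); the exclusion correction is applied at the direct
  same-image distance.
* **Torsions**: cosine terms (V/2)(1 + cos(nφ − γ)) per rotatable-bond
  type.

Analytic Cartesian forces are implemented for the nonbonded terms and
verified against central finite differences to 1e-4 relative. Stress is
obtained by central finite differences over the six symmetric strain
components (step 1e-4), with the molecule responding rigidly — exactly
the cell degrees of freedom the minimizer varies.

This surrogate deliberately stands in for a dispersion-corrected DFT
engine: the pipeline's structure (reference data → tailor-made fit →
search → rank) is preserved while each energy call costs milliseconds.
Nothing in the package depends on the surrogate's specific functional
form beyond the `ForceField` container.

## Tailor-made force-field fitting

`fit_force_field` adjusts per-pair (ε, σ), per-torsion-type barriers and
an optional constant offset by bounded least squares against reference
energies (and optionally forces). Provenance — residual RMS, reference
hash, rank-deficiency report — is stored on the returned object. A
singular-value screen of the Jacobian names unconstrained parameters
(e.g. pairs for elements absent from the reference set). Parameter
recovery from a noiseless 50-structure reference set generated by the
same functional form is within 1 % starting from a template perturbed by
tens of percent; with Gaussian noise of scale 0.5 kJ/mol the fit
residual RMS reproduces the injected scale.

## Packing search

The parallel-tempering sampler is generic over a system protocol
(energy/propose/quench/key), which is what lets the same machinery be
validated on exactly solvable systems. For crystals the move set is:
symmetry-preserving cell strain, rigid translation, rigid rotation
(quaternion composition with a random-axis rotation), and single-torsion
rotation; torsion moves are refused for rigid molecules. Replicas run
Metropolis sampling on a geometric temperature ladder (default 8
replicas, 300–3000 K) with adjacent-pair swaps every 5 sweeps accepted
with min(1, exp(ΔβΔE)). Non-finite trial energies reset the replica with
a logged event.

Accepted states below a running energy quantile are quenched (locally
minimized) and entered into a rediscovery ledger keyed by rounded energy
plus packing fingerprint. The stopping rule — converged when each of the
k lowest distinct minima has been independently rediscovered at least m
times (defaults k = 3, m = 3) — is this package's concrete
interpretation of statistical convergence control; raising m can only
lengthen a run (tested). Correctness is established on two oracles: a
finite discrete system whose Boltzmann distribution is enumerable
(per-replica visit frequencies match within 3σ multinomial bounds, with
visits thinned to every 10th sweep so the tallies are effectively
independent draws), and a separable two-torsion potential
v(φ) = a(1 + cos φ) + b(1 + cos 3φ) whose unique global minimum (180°,
180°, E = 0) is recovered in ≥ 95 of 100 seeded runs. Runs are bitwise
reproducible from the seed.

## Local minimization and the convergence contract

Minimization of H = E + p·V runs L-BFGS-B on the reduced coordinate
vector (free cell parameters, centroid, quaternion, torsions; angles and
torsions scaled by 30° per optimizer unit, centroid by 0.2 fractional
units). Near-degenerate cells are kept out by a smooth penalty on the
metric discriminant rather than a flat cliff, so trial steps that shear
the cell too far feel a restoring gradient. The quaternion is
renormalized inside the objective; the centroid is wrapped into [0, 1).
Cell and/or torsions can be frozen (used by the disorder module).

Success requires four simultaneous criteria, defaults 0.003 Å maximum
atomic displacement between the final iterations, 0.001 kJ/mol per atom
energy change, 1.7 kJ mol⁻¹ Å⁻¹ maximum atomic force and 0.0125 kbar
cell-stress residual. In a rigid-fragment model the raw atomic forces
contain bond-constraint components that never vanish, so the force
criterion is evaluated on the projected driving force F = J(JᵀJ)⁻¹g —
the Cartesian force field realizable by the free degrees of freedom
(J is the position Jacobian, g the reduced gradient) — and the stress
criterion on (σ + p·I) projected onto the lattice system's allowed
strains. Both projections reduce to the usual quantities when all
degrees of freedom are free, and both vanish exactly at a constrained
minimum, which is the transferable content of the four-tolerance
contract. Hitting the iteration cap (default 2000) returns the best
state flagged unconverged, never silently converged. A 1D toy whose
analytic minimum is known (single LJ site with one short cell axis)
converges to the pair-potential minimum distance within 1e-4 Å.

## Landscape analytics

Packing similarity is the RMS deviation between sorted lists of the 24
nearest intermolecular centroid–centroid distances (within 12 Å) around
a reference molecule. This fingerprint is invariant under any
re-description of the same packing — supercells, re-settings, axis
relabelings — because the neighbour-distance multiset is a property of
the packing, not of the cell choice; no explicit cell reduction is
therefore required, and a supercell test asserts the invariance.
Duplicates (energy within 0.1 kJ/mol *and* fingerprint within 0.1 Å)
keep the lower-energy member. Families are single-linkage clusters at a
looser 0.5 Å cut — conformational variants of one packing barely move
the centroids, while genuinely different packings differ by well over
0.5 Å on the synthetic fixtures — and each family is named after its
lowest-energy member.

Landscapes are ranked ascending by energy (ties: higher density first,
then label), truncated to the top N, and mean-calibrated so the average
relative lattice energy is zero; the calibration is idempotent and
shift-invariant. Pressure scans re-minimize each structure on the grid
0.0–1.0 GPa in 0.2 GPa steps (warm-started from the previous pressure),
apply per-pressure mean calibration, and flag unconverged points rather
than interpolating. Crossings of ΔH(p) against a named reference are
located by bisection on the piecewise-linear interpolant to 1e-3 GPa;
a constructed two-structure system with closed-form crossing pressure
p* = (E_B − E_A)/((V_A − V_B)·0.602214) is recovered to that tolerance.
`compare_rankings` mean-centers both energy lists before averaging |ΔE|
(landscapes are reported as calibrated relative energies); the raw
deviation and the Spearman rank correlation are reported alongside.

## Configurational disorder

A disordered form is modelled as a host lattice whose molecular site is
thermally populated by the conformations of its family members: each
member's torsion vector is substituted into the host and the molecular
placement relaxed with the cell frozen and the torsions held fixed (the
conformations *are* the configurations). Under the independent-site
approximation — each site chooses independently, no inter-site coupling,
no vibrational contribution — the free energy per molecule is
F = E_min − RT·ln Σ g_i·exp(−(E_i − E_min)/RT), computed in shifted form
for stability; degeneracies default to 1. F ≤ min E_i always, F → min E_i
as T → 0⁺, and ∂F/∂T = −S ≤ 0. The default temperature is 295 K
(ambient). The mechanism this captures: a family with several thermally
accessible conformations gains −TS_config and can overtake an ordered
competitor of equal or even lower lattice energy — asserted on a
constructed host pair. The independent-site approximation is the model's
central simplification; coupled-site statistical mechanics is a
non-goal.

## Synthetic study systems and problem sizes

All fixtures are generated from seeds at run time: chain-like toy
molecules (n torsions + 3 carbon-like atoms, zig-zag reference
conformation, alternating partial charges shifted to exact neutrality,
default scale 0.08 e; n = 10 reproduces the flexibility class of a
highly flexible drug molecule), the rock-salt Ewald oracle with its
Evjen-summed energy, fit datasets of randomized P1 packings, and a
two-family P2₁/c fixture whose members differ only in a tail torsion
while the families differ in cell and molecular placement (the analogue
of chain neighbours related by a screw axis versus a glide plane), with
planted exact duplicates and bundled ground-truth labels.

Problem sizes are chosen so the full suite and the acceptance script run
in minutes on one CPU: molecules of 3–13 atoms, Z ≤ 4, screens of tens
of sweeps, fit sets of 50 structures, 100-seed hit-rate studies. What
passing tests show is that every stage is *correct* on systems where the
answer is known exactly — group closure, Madelung energies, Boltzmann
statistics, parameter recovery, analytic crossing pressures. What they
do not show is chemical accuracy for real molecules: the surrogate has
no polarization, no many-body dispersion, no vibrational free energy,
and the toy molecules do not emulate hydrogen bonding or real torsion
profiles. Real ranking fidelity is inherited from whatever reference
data the tailor-made fit is given.

## Known limitations

* Rigid bonds/angles; torsions are the only internal degrees of freedom.
* One canonical setting per space group; no Z′ > 1, no special
  positions, no solvates/cocrystals.
* Minimizer gradients are finite-difference on the reduced coordinates;
  analytic derivatives exist only for the nonbonded Cartesian forces.
* No phonon check that minima are true minima (flagged as unchecked in
  the convergence report semantics).
* The disorder model ignores inter-site coupling and vibrational
  entropy.
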