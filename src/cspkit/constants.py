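"""Physical constants in the package's working units.

Energies are kJ/mol per molecule, distances Å, charges in elementary
charge units, pressures GPa externally (kbar for stress residuals).
"""

#: Avogadro constant, 1/mol.
N_A = 6.02214076e23

#: Coulomb constant e^2/(4 pi eps0) * N_A in kJ mol^-1 Å e^-2.
K_E = 1389.35457644382

#: Molar gas constant in kJ mol^-1 K^-1.
R_GAS = 8.31446261815324e-3

#: Boltzmann constant in the same molar units (identical to R_GAS).
K_B = R_GAS

#: 1 GPa * Å^3 expressed in kJ/mol (pV work per molecule).
GPA_A3_TO_KJ_MOL = 0.602214076

#: 1 kJ mol^-1 Å^-3 expressed in kbar (stress unit conversion).
KJ_MOL_A3_TO_KBAR = 1.0 / GPA_A3_TO_KJ_MOL * 10.0

#: Madelung constant of the rock-salt lattice (per ion pair, nearest-
#: neighbour distance as the length scale).
MADELUNG_NACL = 1.7475645946331822
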