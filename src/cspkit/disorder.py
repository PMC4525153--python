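"""Configurational-disorder free energy by Boltzmann population.

A disordered crystal form is modelled as one host lattice whose
molecular site can adopt several conformations: each family member's
conformation is substituted into the host cell and relaxed with the
cell held fixed, giving configuration energies E_i. Under the
independent-site approximation (each site chooses its configuration
independently; no inter-site coupling) the configurational free energy
per molecule is

    F = -RT ln Σ_i g_i exp(-(E_i - E_min)/RT) + E_min

with populations p_i ∝ g_i exp(-E_i/RT). Disorder can therefore make a
form with a *higher* lattice energy the more stable one at temperature —
the mechanism by which a family with many thermally accessible
conformations beats an energetically close but conformationally rigid
competitor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import R_GAS
from .energy import ForceField
from .minimize import minimize_lattice
from .structures import CrystalStructure

__all__ = [
    "Configuration",
    "DisorderModel",
    "enumerate_configurations",
    "config_free_energy",
]

#: ambient temperature (K) of the reference experiments
DEFAULT_TEMPERATURE = 295.0


@dataclass
class Configuration:
    """One thermally accessible molecular configuration in the host."""

    label: str
    energy: float              # relaxed lattice energy, kJ/mol per molecule
    degeneracy: int = 1
    structure: CrystalStructure | None = None


@dataclass
class DisorderModel:
    """Result bundle: configurations, populations and free energy."""

    host: str
    configurations: list
    temperature: float
    free_energy: float
    populations: np.ndarray = field(default=None)

    def population_of(self, label: str) -> float:
        for c, p in zip(self.configurations, self.populations):
            if c.label == label:
                return float(p)
        raise KeyError(label)


def enumerate_configurations(family: list, host_label: str, ff: ForceField,
                             drop_threshold: float = 50.0,
                             max_iterations: int = 600,
                             log: list | None = None) -> list:
    """Relax every family member's conformation in the host's fixed cell.

    ``family`` is a list of structures belonging to one packing family;
    the member labelled ``host_label`` provides the cell. Each member's
    torsion angles (its conformation — held fixed, since the distinct
    conformations *are* the configurations) are substituted into the
    host, and the molecular placement is relaxed with the cell frozen.
    Configurations whose relaxed energy still exceeds the host's by
    ``drop_threshold`` kJ/mol (unresolvable overlap) are dropped with a
    logged reason. The host's own configuration comes first.
    """
    hosts = [s for s in family if s.label == host_label]
    if not hosts:
        raise ValueError(f"host {host_label!r} is not a family member")
    host = hosts[0]
    host_res = minimize_lattice(host, ff, freeze_cell=True,
                                freeze_torsions=True,
                                max_iterations=max_iterations)
    host_e = host_res.breakdown.total
    configs = [Configuration(host_label, host_e, structure=host_res.structure)]
    for member in family:
        if member.label == host_label:
            continue
        trial = host.replace(torsion_angles=np.array(member.torsion_angles),
                             label=f"{host_label}<-{member.label}")
        res = minimize_lattice(trial, ff, freeze_cell=True,
                               freeze_torsions=True,
                               max_iterations=max_iterations)
        e = res.breakdown.total
        if not math.isfinite(e) or e - host_e > drop_threshold:
            if log is not None:
                log.append((member.label, "dropped: unresolvable overlap "
                            f"(relaxed E exceeds host by {e - host_e:.1f} kJ/mol)"))
            continue
        configs.append(Configuration(trial.label, e, structure=res.structure))
    return configs


def config_free_energy(configs: list, temperature: float = DEFAULT_TEMPERATURE,
                       host: str = "") -> DisorderModel:
    """Free energy and populations of a configuration set.

    Evaluated in energy-shifted form for numerical stability:
    F = E_min - RT ln Σ g_i exp(-(E_i - E_min)/RT). Single-configuration
    sets give F = E_1 exactly; F never exceeds min_i E_i.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    e = np.array([c.energy for c in configs], float)
    g = np.array([c.degeneracy for c in configs], float)
    rt = R_GAS * temperature
    e_min = e.min()
    log_z = logsumexp(-(e - e_min) / rt, b=g)
    f = e_min - rt * log_z
    log_p = np.log(g) - (e - e_min) / rt - log_z
    p = np.exp(log_p)
    p = p / p.sum()
    return DisorderModel(host=host or configs[0].label,
                         configurations=list(configs),
                         temperature=temperature,
                         free_energy=float(f),
                         populations=p)
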