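"""Landscape analytics: deduplication, families, diagrams, pressure scans.

Implements the post-processing behind an energy-density polymorph
landscape: collapse duplicate minima, cluster conformational variants of
one packing into families (named after their lowest-energy member), rank
the survivors with mean-calibrated relative energies, re-rank under
hydrostatic pressure on a grid with enthalpy-crossing detection, and
compare lattice-energy rankings between two methods.

Packing similarity uses the sorted list of intermolecular centroid-
centroid distances around a reference molecule (a description-invariant
fingerprint: any supercell or re-setting of the same packing yields the
same list, which is why no explicit cell reduction is needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

from .energy import ForceField
from .minimize import MinimizeResult, ToleranceSet, minimize_lattice
from .structures import CrystalStructure, cell_volume, density
from .symmetry import expand_asymmetric_unit, get_setting

__all__ = [
    "packing_fingerprint",
    "structure_fingerprint",
    "fingerprint_distance",
    "deduplicate",
    "cluster_families",
    "build_landscape",
    "pressure_scan",
    "find_crossings",
    "compare_rankings",
    "RankingComparison",
    "DEFAULT_PRESSURE_GRID",
]

#: pressure grid in GPa
DEFAULT_PRESSURE_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.2), 10)


def packing_fingerprint(M: np.ndarray, centroids_frac: np.ndarray,
                        radius: float = 12.0, k: int = 24) -> np.ndarray:
    """Sorted distances (Å) from molecule 0 to its k nearest neighbours.

    ``centroids_frac`` holds the molecular centroids of one cell
    description; periodic images within ``radius`` are included. Missing
    entries (fewer than k neighbours in range) are padded with
    ``radius`` so the vector has fixed length.
    """
    centroids_frac = np.atleast_2d(centroids_frac)
    V = abs(np.linalg.det(M))
    a, b, c = M.T
    widths = np.array([
        V / np.linalg.norm(np.cross(b, c)),
        V / np.linalg.norm(np.cross(c, a)),
        V / np.linalg.norm(np.cross(a, b)),
    ])
    nmax = np.ceil(radius / widths).astype(int) + 1
    shifts = np.array([(i, j, l) for i in range(-nmax[0], nmax[0] + 1)
                       for j in range(-nmax[1], nmax[1] + 1)
                       for l in range(-nmax[2], nmax[2] + 1)], dtype=float)
    d_frac = centroids_frac[None, :, :] + shifts[:, None, :] - centroids_frac[0]
    d_cart = d_frac @ M.T
    dist = np.linalg.norm(d_cart, axis=-1).ravel()
    dist = np.sort(dist[dist > 1e-8])
    dist = dist[dist <= radius][:k]
    if len(dist) < k:
        dist = np.concatenate([dist, np.full(k - len(dist), radius)])
    return dist


def structure_fingerprint(structure: CrystalStructure,
                          radius: float = 12.0, k: int = 24) -> np.ndarray:
    frac, _ = expand_asymmetric_unit(structure, hard_core=0.0)
    centroids = frac.mean(axis=1)
    return packing_fingerprint(structure.cell.matrix(), centroids, radius, k)


def fingerprint_distance(f1: np.ndarray, f2: np.ndarray) -> float:
    """RMS deviation between two sorted centroid-distance lists."""
    return float(np.sqrt(np.mean((np.asarray(f1) - np.asarray(f2)) ** 2)))


def _fingerprints(structures, fingerprints):
    if fingerprints is not None:
        return [np.asarray(f) for f in fingerprints]
    return [structure_fingerprint(s) for s in structures]


def deduplicate(structures: list, energies: list,
                e_tol: float = 0.1, d_tol: float = 0.1,
                fingerprints: list | None = None):
    """Collapse duplicate minima; keep the lower-energy member.

    Two structures are duplicates iff their energies differ by less than
    ``e_tol`` (kJ/mol) *and* their packing fingerprints by less than
    ``d_tol`` (Å). Returns ``(kept_indices, representative_of)`` where
    ``representative_of[i]`` maps every input index to its surviving
    representative.
    """
    n = len(structures)
    energies = np.asarray(energies, float)
    fps = _fingerprints(structures, fingerprints)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (abs(energies[i] - energies[j]) < e_tol
                    and fingerprint_distance(fps[i], fps[j]) < d_tol):
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    kept, rep_of = [], {}
    for members in groups.values():
        best = min(members, key=lambda i: (energies[i], i))
        kept.append(best)
        for i in members:
            rep_of[i] = best
    kept.sort(key=lambda i: energies[i])
    return kept, rep_of


def cluster_families(structures: list, energies: list, labels: list,
                     threshold: float = 0.5,
                     fingerprints: list | None = None) -> dict:
    """Single-linkage packing families, ignoring conformational detail.

    The centroid-distance fingerprint is insensitive to torsion-angle
    changes that leave the packing intact, so conformational variants of
    one packing cluster together; the (looser) ``threshold`` is the
    linkage cut in Å. Each family is named after its lowest-energy
    member. Returns label -> family-name.
    """
    n = len(structures)
    energies = np.asarray(energies, float)
    if n == 1:
        return {labels[0]: labels[0]}
    fps = _fingerprints(structures, fingerprints)
    condensed = [fingerprint_distance(fps[i], fps[j])
                 for i in range(n) for j in range(i + 1, n)]
    assign = fcluster(linkage(condensed, method="single"),
                      t=threshold, criterion="distance")
    out = {}
    for fam_id in np.unique(assign):
        members = np.nonzero(assign == fam_id)[0]
        name = labels[members[np.argmin(energies[members])]]
        for i in members:
            out[labels[i]] = name
    return out


def build_landscape(structures: list, energies: list, top_n: int | None = None,
                    families: dict | None = None) -> pd.DataFrame:
    """Ranked, mean-calibrated energy-density table.

    Sorts ascending by energy (ties: higher density first, then label),
    keeps the ``top_n`` most stable structures, assigns 1-based ranks
    and subtracts the mean energy of the kept set so the average
    relative lattice energy is zero.
    """
    n = len(structures)
    top_n = n if top_n is None else top_n
    if top_n > n:
        raise ValueError("top_n exceeds the number of structures")
    rows = []
    for s, e in zip(structures, energies):
        setting = get_setting(s.space_group)
        rows.append({
            "label": s.label,
            "energy": e,
            "density": density(s, setting.multiplicity),
            "space_group": setting.hermann_mauguin,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(["energy", "density", "label"],
                        ascending=[True, False, True], kind="mergesort")
    df = df.head(top_n).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["rel_energy"] = df["energy"] - df["energy"].mean()
    if families:
        df["family"] = df["label"].map(families)
    else:
        df["family"] = df["label"]
    return df[["label", "rank", "rel_energy", "density", "family",
               "space_group", "energy"]]


def pressure_scan(structures: list, ff: ForceField,
                  grid=None, tol: ToleranceSet = ToleranceSet(),
                  max_iterations: int = 2000) -> pd.DataFrame:
    """Re-minimize every structure at each grid pressure (warm-started).

    Returns a long-format table (label, pressure, enthalpy, volume,
    converged, rel_enthalpy) with per-pressure mean calibration over the
    structures that converged at that pressure. Unconverged points are
    kept but flagged, never interpolated.
    """
    grid = DEFAULT_PRESSURE_GRID if grid is None else np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("pressure grid must be strictly increasing")
    rows = []
    for s in structures:
        current = s
        for p in grid:
            res: MinimizeResult = minimize_lattice(
                current, ff, pressure=float(p), tol=tol,
                max_iterations=max_iterations)
            current = res.structure
            setting = get_setting(current.space_group)
            v_mol = cell_volume(current.cell) / setting.multiplicity
            rows.append({
                "label": s.label,
                "pressure": float(p),
                "enthalpy": res.breakdown.total,
                "volume": v_mol,
                "converged": res.report.converged,
            })
    df = pd.DataFrame(rows)
    df["rel_enthalpy"] = np.nan
    for p, sub in df.groupby("pressure"):
        ok = sub["converged"]
        mean = sub.loc[ok, "enthalpy"].mean() if ok.any() else sub["enthalpy"].mean()
        df.loc[sub.index, "rel_enthalpy"] = sub["enthalpy"] - mean
    return df


def find_crossings(profiles: pd.DataFrame, reference: str,
                   refine_tol: float = 1e-3) -> dict:
    """Stability-crossing pressures of every structure vs a reference.

    ΔH(p) between each structure and ``reference`` is interpolated
    piecewise-linearly on the grid; every sign change is located by
    bisection on the interpolant to ``refine_tol`` GPa. Structures with
    no crossing map to an empty list.
    """
    ref = profiles[profiles["label"] == reference].sort_values("pressure")
    if ref.empty:
        raise ValueError(f"reference {reference!r} not in profiles")
    out = {}
    for label, sub in profiles.groupby("label"):
        if label == reference:
            continue
        sub = sub.sort_values("pressure")
        p = sub["pressure"].to_numpy()
        dh = sub["enthalpy"].to_numpy() - ref["enthalpy"].to_numpy()
        crossings = []
        for i in range(len(p) - 1):
            a, b = dh[i], dh[i + 1]
            if a == 0.0:
                crossings.append(float(p[i]))
                continue
            if a * b < 0:
                lo, hi = p[i], p[i + 1]
                flo = a
                # bisection on the piecewise-linear interpolant
                while hi - lo > refine_tol:
                    mid = 0.5 * (lo + hi)
                    fm = np.interp(mid, p, dh)
                    if flo * fm <= 0:
                        hi = mid
                    else:
                        lo, flo = mid, fm
                crossings.append(0.5 * (lo + hi))
        if len(p) and dh[-1] == 0.0:
            crossings.append(float(p[-1]))
        out[label] = crossings
    return out


@dataclass(frozen=True)
class RankingComparison:
    """Agreement between two lattice-energy rankings of one structure set."""

    mean_abs_deviation: float        # after mean-centering both lists
    mean_abs_deviation_raw: float    # on the energies as given
    rank_correlation: float          # Spearman rho
    n: int


def compare_rankings(energies_a: dict, energies_b: dict) -> RankingComparison:
    """Mean absolute lattice-energy deviation between two methods.

    Both energy sets are mean-centered before differencing (landscapes
    are reported as calibrated relative energies); the raw deviation and
    the Spearman rank correlation are reported alongside.
    """
    missing = set(energies_a) ^ set(energies_b)
    if missing:
        raise ValueError(f"label mismatch between rankings: {sorted(missing)}")
    labels = sorted(energies_a)
    a = np.array([energies_a[k] for k in labels], float)
    b = np.array([energies_b[k] for k in labels], float)
    raw = float(np.mean(np.abs(a - b)))
    ac, bc = a - a.mean(), b - b.mean()
    centered = float(np.mean(np.abs(ac - bc)))
    rho = float(spearmanr(a, b).statistic) if len(a) > 2 else math.nan
    return RankingComparison(centered, raw, rho, len(a))
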