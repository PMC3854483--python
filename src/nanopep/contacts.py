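"""Peptide-surface contact statistics, buried contact area, RDFs and RMSF.

* ``contact_stability`` — per residue, the percentage of frames with any
  residue atom strictly within the contact cutoff (default 4 angstrom,
  capturing van der Waals contact) of any surface atom.
* ``buried_contact_area`` — half the solvent-accessible surface area lost
  on complex formation, from a deterministic Shrake-Rupley sampler with a
  fixed sphere-point count (Fibonacci lattice) and Bondi radii.
* ``rdf`` — radial distribution function g(r) between two atom groups,
  normalized by ideal-gas shell counts at the B-group number density so
  that g -> 1 for uncorrelated groups.
* ``rmsf`` — per-residue root-mean-square fluctuation about the time
  average after best-fit superposition of every frame onto the first.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AtomSet,
    AtomTrajectory,
    DegenerateInputError,
    EmptyInputError,
    GeometryError,
    RangeError,
    VDW_RADII,
)
from .clustering import kabsch_rotation

__all__ = ["contact_stability", "sasa", "buried_contact_area", "rdf", "rmsf",
           "fibonacci_sphere"]


# ---------------------------------------------------------------------------
# contact stability


def contact_stability(traj: AtomTrajectory,
                      surface_atom_ids: Optional[Sequence[int]] = None,
                      cutoff: float = 4.0) -> Dict[str, float]:
    """Percent of frames each residue touches the surface (strict < cutoff).

    ``surface_atom_ids`` defaults to the trajectory's "NANO"-labelled atoms.
    """
    if len(traj) == 0:
        raise EmptyInputError("contact_stability requires at least one frame")
    surf = (np.asarray(surface_atom_ids, dtype=int)
            if surface_atom_ids is not None else traj.surface_indices())
    if surf.size == 0:
        raise EmptyInputError("no surface atoms selected")
    residues = [(lab, idx) for lab, idx in traj.residues]
    if not residues:
        raise EmptyInputError("trajectory defines no peptide residues")
    hits = {lab: 0 for lab, _ in residues}
    for f in range(len(traj)):
        xyz = traj.coords[f]
        tree = cKDTree(xyz[surf])
        for lab, idx in residues:
            d, _ = tree.query(xyz[idx], k=1)
            if np.min(d) < cutoff:
                hits[lab] += 1
    n = len(traj)
    return {lab: 100.0 * hits[lab] / n for lab, _ in residues}


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley, deterministic points)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(atoms: AtomSet, probe: float = 1.4, n_points: int = 960) -> float:
    """Total solvent-accessible surface area (angstrom^2).

    Shrake-Rupley style: each atom's probe-expanded sphere is sampled at
    ``n_points`` fixed lattice points; a point is accessible when outside
    every other atom's expanded sphere.
    """
    radii = np.array([VDW_RADII[e.upper()] for e in atoms.elements]) + probe
    pts = fibonacci_sphere(n_points)
    xyz = atoms.coords
    tree = cKDTree(xyz)
    rmax = radii.max()
    total = 0.0
    for i in range(len(xyz)):
        sphere = xyz[i] + radii[i] * pts
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((sphere - xyz[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        total += 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def buried_contact_area(peptide: AtomSet, surface: AtomSet,
                        probe: float = 1.4, n_points: int = 960) -> float:
    """Buried contact area between two disjoint atom sets (angstrom^2).

    Defined as (SASA(peptide) + SASA(surface) - SASA(complex)) / 2 — half
    the accessible area lost on association; zero at large separation.
    """
    cross = cKDTree(peptide.coords).query_ball_tree(cKDTree(surface.coords), r=1e-3)
    if any(cross_i for cross_i in cross):
        raise GeometryError("peptide and surface share (near-)coincident atoms")
    complex_atoms = AtomSet.concatenate([peptide, surface])
    return 0.5 * (sasa(peptide, probe, n_points) + sasa(surface, probe, n_points)
                  - sasa(complex_atoms, probe, n_points))


# ---------------------------------------------------------------------------
# radial distribution function


def rdf(traj: AtomTrajectory, group_a_ids: Sequence[int],
        group_b_ids: Sequence[int], r_max: float,
        bin_width: float = 0.1) -> Tuple[np.ndarray, np.ndarray]:
    """g(r) between groups A and B under the trajectory's periodic cell.

    Distances use the minimum image; counts are normalized per frame and
    per A atom by the ideal-gas shell population ``rho_B * V_shell`` with
    ``rho_B = n_B / V_cell``, so uncorrelated groups give g(r) = 1.
    Self-pairs (indices present in both groups) are excluded.

    Returns ``(bin_centers, g)``.
    """
    a = np.asarray(group_a_ids, dtype=int)
    b = np.asarray(group_b_ids, dtype=int)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("both RDF groups must be non-empty")
    tpl = traj.template
    if tpl.cell is None or not tpl.pbc.any():
        raise RangeError("rdf requires a periodic cell for density normalization")
    lengths = tpl.box_lengths
    if r_max > lengths[tpl.pbc].min() / 2.0 + 1e-9:
        raise RangeError("r_max exceeds half the smallest periodic cell length")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    volume = float(np.prod(lengths))
    rho_b = b.size / volume
    for f in range(len(traj)):
        xyz = traj.coords[f]
        d = tpl.minimum_image(xyz[a][:, None, :] - xyz[b][None, :, :])
        dist = np.linalg.norm(d, axis=-1)
        same = np.isin(a, b)
        if same.any():
            for ia in np.flatnonzero(same):
                dist[ia, np.flatnonzero(b == a[ia])] = np.inf
        counts += np.histogram(dist.ravel(), bins=edges)[0]
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = len(traj) * a.size * rho_b * shells
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / ideal


# ---------------------------------------------------------------------------
# root-mean-square fluctuation


def rmsf(traj: AtomTrajectory) -> Dict[str, float]:
    """Per-residue RMSF (angstrom) after superposing all frames onto the
    first (Kabsch, all peptide+surface atoms, unweighted).

    The residue value is the square root of the mean (over residue atoms)
    of each atom's mean-square fluctuation about its time average.
    """
    if len(traj) < 2:
        raise DegenerateInputError("rmsf requires at least two frames")
    ref = traj.coords[0]
    ref_c = ref - ref.mean(axis=0)
    aligned = np.empty_like(traj.coords)
    for f in range(len(traj)):
        x = traj.coords[f]
        xc = x - x.mean(axis=0)
        r = kabsch_rotation(ref_c, xc)
        aligned[f] = xc @ r.T
    mean_pos = aligned.mean(axis=0)
    msf = ((aligned - mean_pos) ** 2).sum(axis=-1).mean(axis=0)  # per atom
    residues = traj.residues
    if not residues:
        raise EmptyInputError("trajectory defines no residues")
    return {lab: float(np.sqrt(msf[idx].mean())) for lab, idx in residues}
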