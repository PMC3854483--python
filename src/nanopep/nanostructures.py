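"""Deterministic construction of carbonaceous nanomaterial geometries.

Three idealized sp2-carbon models are generated analytically, without
external coordinate files:

* ``build_c60`` — a C60 fullerene as a truncated icosahedron with the two
  experimental bond lengths (1.40 angstrom for hexagon-hexagon bonds,
  1.46 angstrom for pentagon edges), 60 atoms on a common sphere.
* ``build_armchair_nanotube`` — an open-ended (n,n) armchair single-wall
  tube rolled onto an exact cylinder, built from whole translational cells
  (4n atoms per cell, period sqrt(3)*cc).
* ``build_graphene`` — a flat periodic sheet tiled from the 4-atom
  orthorhombic cell (sqrt(3)*cc by 3*cc).

``detect_rings`` perceives every minimal (chordless) 5- or 6-membered
cycle of the bond graph — the full ring census of these lattices — with
periodic images honored for periodic cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import (
    AtomSet,
    GeometryError,
    InvalidChiralityError,
    MalformedLatticeError,
    RangeError,
    Ring,
)

__all__ = [
    "NanomaterialModel",
    "build_c60",
    "build_armchair_nanotube",
    "build_graphene",
    "detect_rings",
    "bond_pairs",
]

#: default carbon-carbon bond length (angstrom); half of it (0.71) is the
#: face-to-face displacement threshold used by the stacking classifier
DEFAULT_CC = 1.42

#: distance cutoff for bond perception; covers both 1.40 and 1.46 bonds
DEFAULT_BOND_CUTOFF = 1.7


@dataclass
class NanomaterialModel:
    """A carbon-only nanomaterial: atoms plus its perceived aromatic rings."""

    kind: str
    atoms: AtomSet
    rings: List[Ring] = field(default_factory=list)
    cc_bond_length: float = DEFAULT_CC

    def __post_init__(self) -> None:
        if not all(e.upper() == "C" for e in self.atoms.elements):
            raise GeometryError("nanomaterial models must be carbon-only")

    @property
    def hexagonal_rings(self) -> List[Ring]:
        return [r for r in self.rings if r.size == 6]

    @property
    def pentagonal_rings(self) -> List[Ring]:
        return [r for r in self.rings if r.size == 5]


def _carbon_atomset(coords: np.ndarray, cell=None, pbc=None) -> AtomSet:
    n = len(coords)
    return AtomSet(
        elements=np.full(n, "C", dtype=object),
        coords=np.asarray(coords, dtype=float),
        group_labels=np.full(n, "NANO", dtype=object),
        cell=cell,
        pbc=np.zeros(3, dtype=bool) if pbc is None else np.asarray(pbc, bool),
    )


# ---------------------------------------------------------------------------
# C60


def build_c60(hex_hex_bond: float = 1.40, pent_bond: float = 1.46) -> NanomaterialModel:
    """Build C60 as a truncated icosahedron centered at the origin.

    The construction starts from a regular icosahedron of edge length
    ``L = hex_hex_bond + 2*pent_bond`` and truncates each edge at fractional
    position ``t = pent_bond / L`` from each end: the surviving middle
    segment of every icosahedron edge becomes a hexagon-hexagon bond of
    length ``hex_hex_bond`` and each pentagon edge has length ``pent_bond``.
    Vertex transitivity of the truncated icosahedron puts all 60 atoms on a
    common sphere (circumradius ~3.56 angstrom for the default bonds).
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    base = []
    for a, b in itertools.product((1.0, -1.0), repeat=2):
        base.extend([(0.0, a, b * phi), (a, b * phi, 0.0), (a * phi, 0.0, b)])
    ico = np.array(base)  # 12 vertices, edge length 2
    L = hex_hex_bond + 2.0 * pent_bond
    t = pent_bond / L
    ico *= L / 2.0

    # directed edges -> one truncation vertex each (60 total)
    d2 = np.sum((ico[:, None, :] - ico[None, :, :]) ** 2, axis=-1)
    edge_len2 = (L) ** 2  # icosahedron edge after scaling
    verts = []
    for i in range(12):
        for j in range(12):
            if i != j and abs(d2[i, j] - edge_len2) < 1e-6 * edge_len2:
                verts.append(ico[i] + t * (ico[j] - ico[i]))
    coords = np.asarray(verts)
    assert coords.shape == (60, 3)
    coords -= coords.mean(axis=0)
    atoms = _carbon_atomset(coords)
    model = NanomaterialModel(kind="fullerene", atoms=atoms,
                              cc_bond_length=hex_hex_bond)
    model.rings = detect_rings(atoms)
    return model


# ---------------------------------------------------------------------------
# armchair nanotube


def build_armchair_nanotube(n: int = 5, min_length: float = 38.0,
                            cc_bond_length: float = DEFAULT_CC) -> NanomaterialModel:
    """Build an open-ended (n,n) armchair tube aligned to the z axis.

    The tube is rolled onto an exact cylinder of radius ``3*n*cc/(2*pi)``
    (arc lengths on the cylinder preserve the flat-sheet bond pattern) and
    assembled from the fewest whole translational cells — 4n atoms each,
    period ``sqrt(3)*cc`` — whose combined length reaches ``min_length``.
    """
    if n < 2:
        raise InvalidChiralityError(f"armchair index n must be >= 2, got {n}")
    if min_length <= 0 or cc_bond_length <= 0:
        raise RangeError("min_length and cc_bond_length must be positive")
    cc = cc_bond_length
    period = np.sqrt(3.0) * cc
    n_cells = int(np.ceil(min_length / period - 1e-12))
    circumference = 3.0 * n * cc
    radius = circumference / (2.0 * np.pi)

    # flat-sheet x positions (units of cc) for the two rows of one cell
    row0 = np.array([x for m in range(n) for x in (3 * m, 3 * m + 1)], float)
    row1 = row0 + 1.5
    coords = []
    for k in range(n_cells):
        for row, dz in ((row0, 0.0), (row1, period / 2.0)):
            theta = 2.0 * np.pi * (row * cc) / circumference
            z = k * period + dz
            for th in theta:
                coords.append((radius * np.cos(th), radius * np.sin(th), z))
    atoms = _carbon_atomset(np.asarray(coords))
    model = NanomaterialModel(kind="nanotube", atoms=atoms, cc_bond_length=cc)
    model.rings = detect_rings(atoms)
    return model


# ---------------------------------------------------------------------------
# graphene


def build_graphene(min_x: float = 60.0, min_y: float = 60.0,
                   cc_bond_length: float = DEFAULT_CC,
                   nx: Optional[int] = None, ny: Optional[int] = None,
                   slab_height: float = 60.0) -> NanomaterialModel:
    """Build a flat periodic graphene sheet at z = 0.

    The sheet tiles the 4-atom orthorhombic cell (``sqrt(3)*cc`` by
    ``3*cc``); replication counts are the smallest whole numbers covering
    ``min_x`` by ``min_y`` (ceiling per axis — no partial hexagons), unless
    given explicitly via ``nx``/``ny``. The returned cell is periodic in x
    and y; ``slab_height`` sets the non-periodic z extent.
    """
    if min_x <= 0 or min_y <= 0:
        raise RangeError("min_x and min_y must be positive")
    cc = cc_bond_length
    ax, ay = np.sqrt(3.0) * cc, 3.0 * cc
    if nx is None:
        nx = int(np.ceil(min_x / ax - 1e-12))
    if ny is None:
        ny = int(np.ceil(min_y / ay - 1e-12))
    basis = np.array([
        [0.0, 0.0, 0.0],
        [ax / 2.0, cc / 2.0, 0.0],
        [ax / 2.0, 1.5 * cc, 0.0],
        [0.0, 2.0 * cc, 0.0],
    ])
    shifts = np.array([[i * ax, j * ay, 0.0]
                       for i in range(nx) for j in range(ny)])
    coords = (shifts[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    cell = np.diag([nx * ax, ny * ay, slab_height])
    atoms = _carbon_atomset(coords, cell=cell, pbc=[True, True, False])
    model = NanomaterialModel(kind="graphene", atoms=atoms, cc_bond_length=cc)
    model.rings = detect_rings(atoms)
    return model


# ---------------------------------------------------------------------------
# ring perception


def bond_pairs(atoms: AtomSet, bond_cutoff: float = DEFAULT_BOND_CUTOFF) -> np.ndarray:
    """All atom-index pairs closer than ``bond_cutoff`` (minimum image)."""
    n = atoms.n_atoms
    pairs = []
    chunk = 512
    for start in range(0, n, chunk):
        block = atoms.coords[start:start + chunk]
        d = atoms.minimum_image(block[:, None, :] - atoms.coords[None, :, :])
        dist = np.linalg.norm(d, axis=-1)
        ii, jj = np.nonzero(dist < bond_cutoff)
        for i, j in zip(ii + start, jj):
            if i < j:
                pairs.append((int(i), int(j)))
    return np.asarray(sorted(pairs), dtype=int).reshape(-1, 2)


def _unwrapped_ring_coords(atoms: AtomSet, cycle) -> np.ndarray:
    pts = [atoms.coords[cycle[0]].copy()]
    for a, b in zip(cycle, cycle[1:]):
        step = atoms.minimum_image(atoms.coords[b] - atoms.coords[a])
        pts.append(pts[-1] + step)
    return np.asarray(pts)


def _ring_from_cycle(atoms: AtomSet, cycle,
                     orient_toward: Optional[np.ndarray]) -> Ring:
    pts = _unwrapped_ring_coords(atoms, cycle)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[-1]
    if orient_toward is not None:
        ref = np.asarray(orient_toward, dtype=float) - centroid
        if np.dot(normal, ref) < 0:
            normal = -normal
    else:
        # +z dominant; fall back to largest-magnitude component positive
        if abs(normal[2]) > 1e-6:
            if normal[2] < 0:
                normal = -normal
        elif normal[np.argmax(np.abs(normal))] < 0:
            normal = -normal
    normal = normal / np.linalg.norm(normal)
    return Ring(member_ids=tuple(int(c) for c in cycle),
                centroid=centroid, normal=normal)


def detect_rings(atoms: AtomSet, bond_cutoff: float = DEFAULT_BOND_CUTOFF,
                 orient_toward: Optional[np.ndarray] = None) -> List[Ring]:
    """Perceive all minimal 5-/6-membered rings of a carbon-only AtomSet.

    Bonds are atom pairs within ``bond_cutoff`` (minimum image under the
    periodic cell, if any). Every chordless cycle of length 5 or 6 is
    returned — for ideal graphitic lattices this equals the face census
    (e.g. 12 pentagons + 20 hexagons for C60). Normals are best-fit-plane
    unit vectors, oriented toward ``orient_toward`` when given, else
    +z-dominant.

    Raises
    ------
    MalformedLatticeError
        If any atom has bond degree above 3 (not a graphitic lattice).
    RangeError
        If ``bond_cutoff`` is outside (1.2, 1.7] angstrom.
    """
    if not all(e.upper() == "C" for e in atoms.elements):
        raise GeometryError("ring perception expects a carbon-only AtomSet")
    if not (1.2 < bond_cutoff <= 1.7):
        raise RangeError("bond_cutoff must lie in (1.2, 1.7] angstrom")
    pairs = bond_pairs(atoms, bond_cutoff)
    adj: "dict[int, list[int]]" = {i: [] for i in range(atoms.n_atoms)}
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    for i, nbrs in adj.items():
        if len(nbrs) > 3:
            raise MalformedLatticeError(
                f"atom {i} has bond degree {len(nbrs)} > 3")
        nbrs.sort()

    cycles: "dict[frozenset, tuple]" = {}
    for a in range(atoms.n_atoms):
        stack = [(a, (a,))]
        while stack:
            node, path = stack.pop()
            for nb in adj[node]:
                if nb == a and len(path) >= 5:
                    key = frozenset(path)
                    if key not in cycles:
                        cycles[key] = path
                elif nb > a and nb not in path and len(path) < 6:
                    stack.append((nb, path + (nb,)))

    edge_set = {frozenset(p) for p in map(tuple, pairs)}
    rings = []
    for members in cycles.values():
        k = len(members)
        ring_edges = {frozenset((members[i], members[(i + 1) % k]))
                      for i in range(k)}
        chord = any(frozenset(p) in edge_set and frozenset(p) not in ring_edges
                    for p in itertools.combinations(members, 2))
        if not chord:
            rings.append(members)
    rings.sort(key=lambda m: tuple(sorted(m)))
    return [_ring_from_cycle(atoms, m, orient_toward) for m in rings]
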