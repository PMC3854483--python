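"""Aromatic-tracking: per-ring pi-stacking state and arrangement categories.

Each peptide aromatic ring (the Tyr and Phe phenyl rings) is classified
per frame against the nanomaterial surface:

* ``NONE`` — minimum ring-atom/surface-atom pairwise distance above the
  contact cutoff (default 4.5 angstrom), or the folded angle between the
  ring normal and the nearest surface ring's normal above the tilt limit
  (default 30 degrees);
* ``FACE_TO_FACE`` — otherwise, if the lateral displacement between the
  peptide-ring centroid and the centroid of the nearest *hexagonal*
  surface ring is below half a C-C bond (default 0.71 angstrom);
* ``OFFSET`` — otherwise.

"Lateral" means in the plane of the partner hexagon: the centroid offset
is projected along the hexagon normal onto its plane. On curved surfaces
(C60, nanotube) the relevant surface normal is that of the nearest ring,
which reduces to the sheet normal on graphene. Pentagons (C60) take part
in the contact and tilt tests but are never face-to-face partners.

The two rings' unordered state pair maps onto six arrangement categories,
1 (no stacking by both) through 6 (face-to-face by both).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    AtomSet,
    AtomTrajectory,
    ClassificationError,
    EmptyInputError,
    Ring,
    SelectionError,
)
from .nanostructures import NanomaterialModel

__all__ = [
    "StackState",
    "StackingParams",
    "RingState",
    "StackingRecord",
    "OccupancyTable",
    "classify_ring",
    "categorize_pair",
    "track_trajectory",
    "occupancy",
    "tracking_map",
    "MAIN_GROUPS",
]


class StackState(str, Enum):
    NONE = "NONE"
    OFFSET = "OFFSET"
    FACE_TO_FACE = "FACE_TO_FACE"


@dataclass(frozen=True)
class StackingParams:
    """Geometric thresholds of the classifier.

    contact_cutoff : angstrom; pairwise ring-atom/surface-atom distance
        above which (strictly) a ring is out of pi-stacking register.
    max_tilt : degrees; folded normal-normal angle above which (strictly)
        a ring is out of register.
    f2f_displacement : angstrom; lateral centroid displacement below which
        (strictly) a registered ring is face-to-face. Ties at the
        threshold count as offset.
    """

    contact_cutoff: float = 4.5
    max_tilt: float = 30.0
    f2f_displacement: float = 0.71

    def __post_init__(self) -> None:
        if min(self.contact_cutoff, self.max_tilt, self.f2f_displacement) <= 0:
            raise ValueError("stacking thresholds must be strictly positive")
        if self.f2f_displacement >= self.contact_cutoff:
            raise ValueError("f2f_displacement must be below contact_cutoff")


@dataclass(frozen=True)
class RingState:
    """Classification of one peptide ring against the surface."""

    value: StackState
    partner_ring: Optional[int]  # index into surface.rings
    tilt: float  # degrees, vs nearest surface ring (folded to [0, 90])
    displacement: float  # angstrom, lateral, vs nearest hexagonal ring
    min_pair_distance: float  # angstrom

    @property
    def stacked(self) -> bool:
        return self.value is not StackState.NONE


@dataclass(frozen=True)
class StackingRecord:
    frame_index: int
    state_tyr: RingState
    state_phe: RingState
    category: int


#: Table S4-style aggregation of the six categories into three main groups
MAIN_GROUPS = {
    "no_stacking": (1,),
    "offset": (2, 3, 4, 5),
    "face_to_face": (6,),
}


#: phenyl ring atom names in cycle order (PDB conventions)
RING_ATOM_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def ring_indices_for_residue(atoms: AtomSet, residue_label: str) -> np.ndarray:
    """Resolve the six phenyl-ring atom indices of one labelled residue
    (e.g. ``"TYR4"``) from atom names, in cycle order."""
    if atoms.names is None:
        raise SelectionError("atom names are required to resolve ring selectors")
    idx = []
    for want in RING_ATOM_NAMES:
        hits = np.flatnonzero((atoms.group_labels == residue_label)
                              & (atoms.names == want))
        if hits.size != 1:
            raise SelectionError(
                f"residue {residue_label!r} does not resolve a phenyl ring "
                f"(atom {want}: {hits.size} matches)")
        idx.append(int(hits[0]))
    return np.asarray(idx, dtype=int)


def _folded_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _ring_coords(ring: Union[np.ndarray, Ring], atoms: Optional[AtomSet]) -> np.ndarray:
    if isinstance(ring, Ring):
        if atoms is None:
            raise SelectionError("a Ring input requires its parent AtomSet")
        coords = atoms.coords[list(ring.member_ids)]
    else:
        coords = np.asarray(ring, dtype=float)
    if coords.shape != (6, 3):
        raise SelectionError(
            f"peptide aromatic ring must have 6 atoms, got shape {coords.shape}")
    return coords


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(coords - coords.mean(axis=0))
    n = vt[-1]
    return n / np.linalg.norm(n)


def classify_ring(ring: Union[np.ndarray, Ring], surface: NanomaterialModel,
                  params: StackingParams = StackingParams(),
                  atoms: Optional[AtomSet] = None) -> RingState:
    """Classify one 6-membered peptide ring against a nanomaterial surface.

    ``ring`` is either a (6, 3) coordinate array or a :class:`Ring` with
    its parent ``atoms``. Distances honor the surface's periodic cell.
    """
    hexes = [(i, r) for i, r in enumerate(surface.rings) if r.size == 6]
    if not hexes:
        raise ClassificationError("surface has no hexagonal rings")
    coords = _ring_coords(ring, atoms)
    centroid = coords.mean(axis=0)
    normal = _plane_normal(coords)
    surf = surface.atoms

    d = surf.minimum_image(coords[:, None, :] - surf.coords[None, :, :])
    min_pair = float(np.linalg.norm(d, axis=-1).min())

    ring_centroids = np.array([r.centroid for r in surface.rings])
    sep = surf.minimum_image(centroid[None, :] - ring_centroids)
    dists = np.linalg.norm(sep, axis=1)
    nearest = int(np.argmin(dists))
    tilt = _folded_angle_deg(normal, surface.rings[nearest].normal)

    hex_ids = np.array([i for i, _ in hexes])
    nearest_hex = int(hex_ids[np.argmin(dists[hex_ids])])
    hx = surface.rings[nearest_hex]
    delta = sep[nearest_hex]
    lateral = delta - np.dot(delta, hx.normal) * hx.normal
    displacement = float(np.linalg.norm(lateral))

    if min_pair > params.contact_cutoff or tilt > params.max_tilt:
        value, partner = StackState.NONE, None
    elif displacement < params.f2f_displacement:
        value, partner = StackState.FACE_TO_FACE, nearest_hex
    else:
        value, partner = StackState.OFFSET, nearest_hex
    return RingState(value=value, partner_ring=partner, tilt=tilt,
                     displacement=displacement, min_pair_distance=min_pair)


_CATEGORY = {
    frozenset({StackState.NONE}): 1,
    frozenset({StackState.OFFSET, StackState.NONE}): 2,
    frozenset({StackState.OFFSET}): 3,
    frozenset({StackState.FACE_TO_FACE, StackState.NONE}): 4,
    frozenset({StackState.FACE_TO_FACE, StackState.OFFSET}): 5,
    frozenset({StackState.FACE_TO_FACE}): 6,
}


def categorize_pair(a: Union[RingState, StackState, str],
                    b: Union[RingState, StackState, str]) -> int:
    """Map the unordered pair of ring states onto arrangement category 1-6."""
    def as_state(x):
        if isinstance(x, RingState):
            return x.value
        return StackState(x)

    return _CATEGORY[frozenset({as_state(a), as_state(b)})]


def _resolve_selectors(traj: AtomTrajectory,
                       selectors: Sequence[Sequence[int]]) -> Tuple[np.ndarray, np.ndarray]:
    if len(selectors) != 2:
        raise SelectionError("exactly two aromatic-ring selectors are required")
    out = []
    for sel in selectors:
        idx = np.asarray(sel, dtype=int).ravel()
        if idx.size != 6:
            raise SelectionError(
                f"aromatic ring selector must resolve to 6 atoms, got {idx.size}")
        if idx.min() < 0 or idx.max() >= traj.n_atoms:
            raise SelectionError("ring selector index out of range")
        out.append(idx)
    return out[0], out[1]


def track_trajectory(traj: AtomTrajectory, surface: NanomaterialModel,
                     aromatic_ring_selectors: Sequence[Sequence[int]],
                     params: StackingParams = StackingParams()) -> List[StackingRecord]:
    """Classify both aromatic rings in every frame, in frame order.

    ``aromatic_ring_selectors`` are two 6-atom index lists (Tyr then Phe)
    into the trajectory's atoms.
    """
    tyr_idx, phe_idx = _resolve_selectors(traj, aromatic_ring_selectors)
    records = []
    for f in range(len(traj)):
        xyz = traj.coords[f]
        s_tyr = classify_ring(xyz[tyr_idx], surface, params)
        s_phe = classify_ring(xyz[phe_idx], surface, params)
        records.append(StackingRecord(
            frame_index=f, state_tyr=s_tyr, state_phe=s_phe,
            category=categorize_pair(s_tyr, s_phe)))
    return records


@dataclass(frozen=True)
class OccupancyTable:
    """Per-category frame occupancy (percent) plus the three main groups."""

    per_category: "dict[int, float]"
    main_groups: "dict[str, float]"
    n_frames: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"category": list(self.per_category),
             "occupancy_percent": list(self.per_category.values())})


def occupancy(records: Sequence[StackingRecord]) -> OccupancyTable:
    """Percentage of frames in each arrangement category (sums to 100)."""
    if not records:
        raise EmptyInputError("occupancy requires at least one record")
    n = len(records)
    counts = {c: 0 for c in range(1, 7)}
    for rec in records:
        counts[rec.category] += 1
    per = {c: 100.0 * counts[c] / n for c in counts}
    groups = {name: sum(per[c] for c in cats)
              for name, cats in MAIN_GROUPS.items()}
    return OccupancyTable(per_category=per, main_groups=groups, n_frames=n)


def tracking_map(traj: AtomTrajectory, surface: NanomaterialModel,
                 aromatic_ring_selectors: Sequence[Sequence[int]],
                 params: StackingParams = StackingParams()) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame peptide center of mass and count of stacked rings (0-2).

    Mirrors the tracking-map plot: where the peptide sits versus how many
    aromatic contacts (offset or face-to-face) it makes there.
    """
    records = track_trajectory(traj, surface, aromatic_ring_selectors, params)
    pep = traj.peptide_indices()
    if pep.size == 0:
        pep = traj.template.atom_ids
    coms = np.array([traj.frame(f).center_of_mass(pep)
                     for f in range(len(traj))]).reshape(-1, 3)
    counts = np.array([int(r.state_tyr.stacked) + int(r.state_phe.stacked)
                       for r in records], dtype=int)
    return coms, counts
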