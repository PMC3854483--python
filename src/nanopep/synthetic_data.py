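"""Synthetic inputs for the analysis pipeline, with ground-truth labels.

Real peptide-nanomaterial trajectories come from long explicit-solvent MD
runs; this module generates small, fully seeded stand-ins that exercise
every downstream operation with known answers:

* an all-atom peptide model (correct per-residue atom composition,
  zwitterionic termini, ionized Asp/Glu; idealized geometry) carrying the
  two aromatic ring index lists (Tyr, Phe);
* single aromatic rings and whole trajectories posed over a nanomaterial
  surface at prescribed height / lateral shift / tilt, each pose verified
  by an independent brute-force geometric check so its stacking label is
  guaranteed;
* per-window reaction-coordinate samples Metropolis-drawn from known
  analytic potentials (flat, harmonic, Morse-like) under the harmonic
  umbrella bias, for WHAM validation against closed-form ground truth;
* hydration-shell point sets (Gaussian shell plus uniform background) for
  RDF validation.

All randomness flows from explicit integer seeds; identical seeds give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    AtomSet,
    AtomTrajectory,
    BOLTZMANN_KCAL,
    KJ_PER_KCAL,
    PoseSpecError,
    SamplerError,
    SequenceError,
)
from .nanostructures import NanomaterialModel
from .wham import DEFAULT_FORCE_CONSTANT, UmbrellaWindow

__all__ = [
    "PeptideModel",
    "PoseSpec",
    "build_peptide_model",
    "place_ring",
    "random_pose_specs",
    "synth_adsorption_trajectory",
    "make_potential",
    "metropolis_sample",
    "sample_biased_windows",
    "synth_hydration_shell",
    "APOC2_SEQUENCE",
]

#: the amyloidogenic apoC-II(60-70) peptide studied throughout
APOC2_SEQUENCE = "MSTYTGIFTDQ"

# ---------------------------------------------------------------------------
# all-atom residue composition
#
# Side-chain atoms (name, element) beyond the shared backbone
# N, H, CA, HA, C, O. Ionizable residues are in their pH-7 forms
# (Asp/Glu deprotonated, Lys/Arg protonated, His neutral).

_SC: Dict[str, List[Tuple[str, str]]] = {
    "G": [("HA2", "H")],
    "A": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("HB3", "H")],
    "V": [("CB", "C"), ("HB", "H"), ("CG1", "C"), ("HG11", "H"), ("HG12", "H"),
          ("HG13", "H"), ("CG2", "C"), ("HG21", "H"), ("HG22", "H"), ("HG23", "H")],
    "L": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG", "H"),
          ("CD1", "C"), ("HD11", "H"), ("HD12", "H"), ("HD13", "H"),
          ("CD2", "C"), ("HD21", "H"), ("HD22", "H"), ("HD23", "H")],
    "I": [("CB", "C"), ("HB", "H"), ("CG1", "C"), ("HG11", "H"), ("HG12", "H"),
          ("CG2", "C"), ("HG21", "H"), ("HG22", "H"), ("HG23", "H"),
          ("CD1", "C"), ("HD11", "H"), ("HD12", "H"), ("HD13", "H")],
    "P": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG1", "H"),
          ("HG2", "H"), ("CD", "C"), ("HD1", "H"), ("HD2", "H")],
    "M": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG1", "H"),
          ("HG2", "H"), ("SD", "S"), ("CE", "C"), ("HE1", "H"), ("HE2", "H"),
          ("HE3", "H")],
    "F": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("CD1", "C"),
          ("HD1", "H"), ("CD2", "C"), ("HD2", "H"), ("CE1", "C"), ("HE1", "H"),
          ("CE2", "C"), ("HE2", "H"), ("CZ", "C"), ("HZ", "H")],
    "Y": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("CD1", "C"),
          ("HD1", "H"), ("CD2", "C"), ("HD2", "H"), ("CE1", "C"), ("HE1", "H"),
          ("CE2", "C"), ("HE2", "H"), ("CZ", "C"), ("OH", "O"), ("HH", "H")],
    "W": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("CD1", "C"),
          ("HD1", "H"), ("CD2", "C"), ("NE1", "N"), ("HE1", "H"), ("CE2", "C"),
          ("CE3", "C"), ("HE3", "H"), ("CZ2", "C"), ("HZ2", "H"), ("CZ3", "C"),
          ("HZ3", "H"), ("CH2", "C"), ("HH2", "H")],
    "S": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("OG", "O"), ("HG", "H")],
    "T": [("CB", "C"), ("HB", "H"), ("OG1", "O"), ("HG1", "H"), ("CG2", "C"),
          ("HG21", "H"), ("HG22", "H"), ("HG23", "H")],
    "C": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("SG", "S"), ("HG", "H")],
    "N": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("OD1", "O"),
          ("ND2", "N"), ("HD21", "H"), ("HD22", "H")],
    "Q": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG1", "H"),
          ("HG2", "H"), ("CD", "C"), ("OE1", "O"), ("NE2", "N"), ("HE21", "H"),
          ("HE22", "H")],
    "D": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("OD1", "O"),
          ("OD2", "O")],
    "E": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG1", "H"),
          ("HG2", "H"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "K": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG1", "H"),
          ("HG2", "H"), ("CD", "C"), ("HD1", "H"), ("HD2", "H"), ("CE", "C"),
          ("HE1", "H"), ("HE2", "H"), ("NZ", "N"), ("HZ1", "H"), ("HZ2", "H"),
          ("HZ3", "H")],
    "R": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("HG1", "H"),
          ("HG2", "H"), ("CD", "C"), ("HD1", "H"), ("HD2", "H"), ("NE", "N"),
          ("HE", "H"), ("CZ", "C"), ("NH1", "N"), ("HH11", "H"), ("HH12", "H"),
          ("NH2", "N"), ("HH21", "H"), ("HH22", "H")],
    "H": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("CG", "C"), ("ND1", "N"),
          ("HD1", "H"), ("CD2", "C"), ("HD2", "H"), ("CE1", "C"), ("HE1", "H"),
          ("NE2", "N")],
}

_THREE = {"G": "GLY", "A": "ALA", "V": "VAL", "L": "LEU", "I": "ILE",
          "P": "PRO", "M": "MET", "F": "PHE", "Y": "TYR", "W": "TRP",
          "S": "SER", "T": "THR", "C": "CYS", "N": "ASN", "Q": "GLN",
          "D": "ASP", "E": "GLU", "K": "LYS", "R": "ARG", "H": "HIS"}

_SIDECHAIN_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

#: aromatic ring atom names in cycle order
_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

_RING_CC = 1.39  # phenyl C-C bond, angstrom


@dataclass
class PeptideModel:
    """Idealized all-atom peptide with its two aromatic-ring index lists."""

    sequence: str
    atoms: AtomSet
    aromatic_rings: "list[list[int]]"
    formal_charge: int

    @property
    def gly_ca_id(self) -> Optional[int]:
        """Atom index of the first glycine alpha-carbon (reaction-coordinate
        anchor), if the sequence contains a glycine."""
        for i, (name, lab) in enumerate(zip(self.atoms.names,
                                            self.atoms.group_labels)):
            if name == "CA" and lab.startswith("GLY"):
                return i
        return None


def _hexagon(center: np.ndarray, e1: np.ndarray, e2: np.ndarray,
             radius: float = _RING_CC, phase: float = 0.0) -> np.ndarray:
    ang = phase + np.deg2rad(60.0) * np.arange(6)
    return center + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))


def build_peptide_model(sequence: str = APOC2_SEQUENCE,
                        zwitterionic: bool = True) -> PeptideModel:
    """Build an extended-backbone all-atom peptide model.

    Composition is contractual (atom counts, elements, residue labels,
    termini protonation, formal charge); the geometry is an idealized
    extended chain whose only carefully built features are the two phenyl
    hexagons of Tyr/Phe (C-C 1.39 angstrom, planar).
    """
    sequence = sequence.upper()
    for letter in sequence:
        if letter not in _SC:
            raise SequenceError(f"unknown residue letter {letter!r}")

    names, elements, labels, coords = [], [], [], []
    rings: "list[list[int]]" = []
    charge = 0
    for ri, letter in enumerate(sequence):
        res3 = _THREE[letter]
        label = f"{res3}{ri + 1}"
        origin = np.array([3.8 * ri, 0.0, 0.0])
        charge += _SIDECHAIN_CHARGE.get(letter, 0)

        backbone = [("N", "N", (0.0, 0.0, 0.0)),
                    ("H", "H", (-0.5, -0.85, 0.0)),
                    ("CA", "C", (1.2, 0.6, 0.0)),
                    ("HA", "H", (1.2, 1.2, 0.85)),
                    ("C", "C", (2.4, -0.2, 0.0)),
                    ("O", "O", (2.4, -1.42, 0.0))]
        if letter == "P":
            backbone = [b for b in backbone if b[0] != "H"]
        if ri == 0 and zwitterionic:
            backbone.insert(2, ("H2", "H", (0.5, -0.85, 0.35)))
            backbone.insert(3, ("H3", "H", (-0.2, 0.5, -0.85)))
            charge += 1
        if ri == len(sequence) - 1 and zwitterionic:
            backbone.append(("OXT", "O", (3.3, 0.5, 0.0)))
            charge -= 1
        for name, elem, off in backbone:
            names.append(name)
            elements.append(elem)
            labels.append(label)
            coords.append(origin + np.asarray(off))

        side = _SC[letter]
        ca = origin + np.array([1.2, 0.6, 0.0])
        ring_positions: Dict[str, np.ndarray] = {}
        if letter in ("F", "Y"):
            ring_center = ca + np.array([0.0, 3.2, 0.0])
            hexagon = _hexagon(ring_center, np.array([1.0, 0.0, 0.0]),
                               np.array([0.0, 1.0, 0.0]),
                               phase=np.deg2rad(-90.0))
            ring_positions = dict(zip(_RING_NAMES, hexagon))
            ring_positions["CB"] = ca + np.array([0.0, 1.5, 0.0])
            # ring substituents radiate outward from the ring center
            for k, nm in enumerate(_RING_NAMES):
                sub = {"CD1": "HD1", "CD2": "HD2", "CE1": "HE1",
                       "CE2": "HE2"}.get(nm)
                if sub:
                    out = ring_positions[nm] - ring_center
                    ring_positions[sub] = ring_positions[nm] + 0.76 * out
            top = ring_positions["CZ"] + (ring_positions["CZ"] - ring_center)
            if letter == "Y":
                ring_positions["OH"] = top
                ring_positions["HH"] = top + np.array([0.0, 0.95, 0.0])
            else:
                ring_positions["HZ"] = top

        k = 0
        for name, elem in side:
            if name in ring_positions:
                pos = ring_positions[name]
            else:
                pos = ca + np.array([0.55 * math.cos(0.9 * k),
                                     1.4 + 0.5 * k,
                                     0.55 * math.sin(0.9 * k) + 0.9])
                k += 1
            names.append(name)
            elements.append(elem)
            labels.append(label)
            coords.append(pos)

        if letter in ("F", "Y"):
            base = len(names) - len(side)
            ring_idx = [base + [n for n, _ in side].index(nm)
                        for nm in _RING_NAMES]
            rings.append(ring_idx)

    atoms = AtomSet(elements=np.asarray(elements, dtype=object),
                    coords=np.asarray(coords),
                    group_labels=np.asarray(labels, dtype=object),
                    names=np.asarray(names, dtype=object))
    return PeptideModel(sequence=sequence, atoms=atoms,
                        aromatic_rings=rings, formal_charge=charge)


# ---------------------------------------------------------------------------
# posed aromatic rings with guaranteed labels


@dataclass(frozen=True)
class PoseSpec:
    """Prescription for posing one phenyl ring over a surface hexagon.

    ``height`` is measured along the anchor hexagon's outward normal from
    its centroid; ``lateral_shift`` along the direction to a neighboring
    hexagon centroid; ``tilt`` rotates the ring about an in-plane axis.
    The parameters must force ``target_state`` under the default stacking
    thresholds (with a safety margin), which :func:`place_ring` verifies.
    """

    target_state: str  # NONE | OFFSET | FACE_TO_FACE
    height: float = 3.4
    lateral_shift: float = 0.0
    tilt: float = 0.0
    seed: int = 0
    anchor_ring: Optional[int] = None


def _outward_normal(surface: NanomaterialModel, ring) -> np.ndarray:
    if surface.kind == "graphene":
        return np.array([0.0, 0.0, 1.0]) if ring.normal[2] >= 0 else -ring.normal
    v = ring.centroid - surface.atoms.coords.mean(axis=0)
    if surface.kind == "nanotube":
        v = np.array([v[0], v[1], 0.0])
    n = ring.normal if np.dot(ring.normal, v) >= 0 else -ring.normal
    return n / np.linalg.norm(n)


def _anchor_frame(surface: NanomaterialModel, anchor_idx: int):
    """Anchor hexagon centroid, outward normal and in-plane shift axis
    (toward the nearest neighboring hexagon centroid)."""
    anchor = surface.rings[anchor_idx]
    n = _outward_normal(surface, anchor)
    best, e1 = None, None
    for i, r in enumerate(surface.rings):
        if i == anchor_idx or r.size != 6:
            continue
        d = surface.atoms.minimum_image(r.centroid - anchor.centroid)
        dist = np.linalg.norm(d)
        if best is None or dist < best:
            lat = d - np.dot(d, n) * n
            if np.linalg.norm(lat) > 1e-6:
                best, e1 = dist, lat / np.linalg.norm(lat)
    if e1 is None:  # isolated hexagon: any in-plane direction
        ref = np.array([1.0, 0.0, 0.0])
        e1 = ref - np.dot(ref, n) * n
        e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return anchor, n, e1, e2


def _default_anchor(surface: NanomaterialModel, which: int = 0) -> int:
    """Deterministic anchor hexagons: two well-separated sites per surface."""
    hex_ids = [i for i, r in enumerate(surface.rings) if r.size == 6]
    cents = np.array([surface.rings[i].centroid for i in hex_ids])
    if surface.kind == "graphene":
        mid = surface.atoms.coords.mean(axis=0)
        target = mid if which == 0 else mid + np.array([8.0, 8.0, 0.0])
        pick = int(np.argmin(np.linalg.norm(cents - target, axis=1)))
    elif surface.kind == "nanotube":
        pick = int(np.argmax(cents[:, 0])) if which == 0 else \
            int(np.argmin(cents[:, 0]))
    else:  # fullerene: top and bottom hexagons
        pick = int(np.argmax(cents[:, 2])) if which == 0 else \
            int(np.argmin(cents[:, 2]))
    return hex_ids[pick]


def _pose_hexagon(surface: NanomaterialModel, spec: PoseSpec) -> np.ndarray:
    anchor_idx = spec.anchor_ring
    if anchor_idx is None:
        anchor_idx = _default_anchor(surface, 0)
    if surface.rings[anchor_idx].size != 6:
        raise PoseSpecError("anchor ring must be hexagonal")
    anchor, n, e1, e2 = _anchor_frame(surface, anchor_idx)
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    center = anchor.centroid + spec.height * n + spec.lateral_shift * e1
    pts = _hexagon(center, e1, e2, radius=_RING_CC, phase=phase)
    if abs(spec.tilt) > 1e-12:
        th = np.deg2rad(spec.tilt)
        axis = e2
        rel = pts - center
        # Rodrigues rotation about the in-plane axis through the center
        pts = center + (rel * np.cos(th)
                        + np.cross(axis, rel) * np.sin(th)
                        + np.outer(rel @ axis, axis) * (1.0 - np.cos(th)))
    return pts


# --- independent brute-force classifier (no shared code with `stacking`) ---


def _brute_classify(ring_coords: np.ndarray, surface: NanomaterialModel,
                    contact_cutoff: float = 4.5, max_tilt: float = 30.0,
                    f2f_displacement: float = 0.71,
                    margins: Optional[Tuple[float, float, float]] = None) -> str:
    """Plain-loop reference classification; with ``margins`` it raises
    PoseSpecError whenever any criterion sits within the margin of its
    threshold (so the label would not be robust to small jitter)."""
    box = None
    if surface.atoms.cell is not None and surface.atoms.pbc.any():
        box = [float(np.diag(surface.atoms.cell)[ax]) if surface.atoms.pbc[ax]
               else None for ax in range(3)]

    def mi(vec):
        out = list(vec)
        if box:
            for ax in range(3):
                if box[ax]:
                    out[ax] -= box[ax] * round(out[ax] / box[ax])
        return out

    def dist(p, q):
        d = mi([p[0] - q[0], p[1] - q[1], p[2] - q[2]])
        return math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)

    ring_coords = np.asarray(ring_coords, float)
    centroid = ring_coords.mean(axis=0)
    u = ring_coords[1] - ring_coords[0]
    v = ring_coords[2] - ring_coords[0]
    nvec = np.cross(u, v)
    nvec = nvec / np.linalg.norm(nvec)

    min_pair = min(dist(p, q) for p in ring_coords for q in surface.atoms.coords)

    near_i, near_d = None, None
    for i, r in enumerate(surface.rings):
        d = dist(centroid, r.centroid)
        if near_d is None or d < near_d:
            near_i, near_d = i, d
    rn = surface.rings[near_i].normal
    cosang = abs(float(np.dot(nvec, rn)))
    tilt = math.degrees(math.acos(min(1.0, cosang)))

    hex_i, hex_d = None, None
    for i, r in enumerate(surface.rings):
        if r.size != 6:
            continue
        d = dist(centroid, r.centroid)
        if hex_d is None or d < hex_d:
            hex_i, hex_d = i, d
    hring = surface.rings[hex_i]
    delta = np.asarray(mi(centroid - hring.centroid))
    lateral = delta - np.dot(delta, hring.normal) * hring.normal
    disp = float(np.linalg.norm(lateral))

    if margins is not None:
        m_d, m_a, m_s = margins
        if (abs(min_pair - contact_cutoff) < m_d or abs(tilt - max_tilt) < m_a
                or (min_pair <= contact_cutoff and tilt <= max_tilt
                    and abs(disp - f2f_displacement) < m_s)):
            raise PoseSpecError(
                f"pose sits within margin of a threshold (min_pair={min_pair:.2f}, "
                f"tilt={tilt:.1f}, displacement={disp:.2f})")

    if min_pair > contact_cutoff or tilt > max_tilt:
        return "NONE"
    if disp < f2f_displacement:
        return "FACE_TO_FACE"
    return "OFFSET"


def place_ring(surface: NanomaterialModel, spec: PoseSpec,
               margins: Tuple[float, float, float] = (0.15, 3.0, 0.12),
               ) -> Tuple[AtomSet, str]:
    """Pose a 6-carbon phenyl ring per ``spec`` and return it with its
    guaranteed stacking label.

    The realized pose is verified by an independent brute-force
    classification requiring each criterion to clear its threshold by
    ``margins`` (distance angstrom, angle degrees, displacement angstrom);
    an inconsistent spec raises :class:`PoseSpecError`.
    """
    pts = _pose_hexagon(surface, spec)
    label = _brute_classify(pts, surface, margins=margins)
    if label != spec.target_state:
        raise PoseSpecError(
            f"pose parameters force {label}, not {spec.target_state}")
    n = len(pts)
    atoms = AtomSet(elements=np.full(n, "C", dtype=object), coords=pts,
                    group_labels=np.full(n, "RING1", dtype=object),
                    cell=None if surface.atoms.cell is None
                    else surface.atoms.cell.copy(),
                    pbc=surface.atoms.pbc.copy())
    return atoms, label


def random_pose_specs(n: int, seed: int = 0,
                      states: Sequence[str] = ("NONE", "OFFSET", "FACE_TO_FACE"),
                      anchor_ring: Optional[int] = None) -> List[PoseSpec]:
    """Seeded random pose specifications, each valid by construction.

    Parameter ranges keep every pose clear of the classification
    thresholds: face-to-face shifts stay under 0.45 angstrom, offset
    shifts in [0.95, 1.15] (still nearest to the anchor hexagon), and
    no-stacking poses are either lifted beyond 5.2 angstrom or tilted
    38-55 degrees.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        state = states[int(rng.integers(len(states)))]
        if state == "FACE_TO_FACE":
            spec = PoseSpec(state, height=rng.uniform(3.2, 3.8),
                            lateral_shift=rng.uniform(0.0, 0.45),
                            tilt=rng.uniform(0.0, 15.0),
                            seed=int(rng.integers(2 ** 31)),
                            anchor_ring=anchor_ring)
        elif state == "OFFSET":
            spec = PoseSpec(state, height=rng.uniform(3.2, 3.8),
                            lateral_shift=rng.uniform(0.95, 1.15),
                            tilt=rng.uniform(0.0, 15.0),
                            seed=int(rng.integers(2 ** 31)),
                            anchor_ring=anchor_ring)
        elif rng.random() < 0.5:
            spec = PoseSpec("NONE", height=rng.uniform(5.3, 7.0),
                            lateral_shift=rng.uniform(0.0, 0.8),
                            tilt=rng.uniform(0.0, 15.0),
                            seed=int(rng.integers(2 ** 31)),
                            anchor_ring=anchor_ring)
        else:
            spec = PoseSpec("NONE", height=rng.uniform(3.3, 3.8),
                            lateral_shift=rng.uniform(0.0, 0.35),
                            tilt=rng.uniform(38.0, 55.0),
                            seed=int(rng.integers(2 ** 31)),
                            anchor_ring=anchor_ring)
        specs.append(spec)
    return specs


def synth_adsorption_trajectory(peptide: PeptideModel,
                                surface: NanomaterialModel,
                                schedule: Sequence[Tuple[PoseSpec, PoseSpec]],
                                seed: int = 0,
                                jitter_sigma: float = 0.05,
                                ) -> Tuple[AtomTrajectory, List[dict]]:
    """Frames posing the peptide's two aromatic rings per schedule.

    Each schedule entry is a (Tyr spec, Phe spec) pair; unanchored specs
    are pinned to two well-separated default hexagons. Ring atoms take the
    exact posed hexagon coordinates; the remaining peptide atoms ride
    rigidly well above the first ring (their geometry does not enter the
    classification). Seeded Gaussian jitter of ``jitter_sigma`` angstrom
    is added to every atom — small enough, given the pose margins, to
    provably preserve the labels.

    Returns the trajectory and the per-frame ground truth
    ``{"tyr", "phe", "category"}``.
    """
    if len(peptide.aromatic_rings) != 2:
        raise PoseSpecError("peptide must carry exactly two aromatic rings")
    cat = {frozenset({"NONE"}): 1,
           frozenset({"OFFSET", "NONE"}): 2,
           frozenset({"OFFSET"}): 3,
           frozenset({"FACE_TO_FACE", "NONE"}): 4,
           frozenset({"FACE_TO_FACE", "OFFSET"}): 5,
           frozenset({"FACE_TO_FACE"}): 6}
    rng = np.random.default_rng(seed)
    anchors = (_default_anchor(surface, 0), _default_anchor(surface, 1))
    n_atoms = peptide.atoms.n_atoms
    ring_idx = [np.asarray(r, dtype=int) for r in peptide.aromatic_rings]
    other = np.setdiff1d(np.arange(n_atoms), np.concatenate(ring_idx))

    frames = np.empty((len(schedule), n_atoms, 3))
    labels = []
    for f, pair in enumerate(schedule):
        coords = peptide.atoms.coords.copy()
        states = []
        for which, spec in enumerate(pair):
            if spec.anchor_ring is None:
                spec = PoseSpec(spec.target_state, spec.height,
                                spec.lateral_shift, spec.tilt, spec.seed,
                                anchor_ring=anchors[which])
            posed, label = place_ring(surface, spec)
            coords[ring_idx[which]] = posed.coords
            states.append(label)
        # park the rest of the chain well above the first ring
        a0, n0, _, _ = _anchor_frame(surface, anchors[0])
        rest_target = a0.centroid + 12.0 * n0
        coords[other] += rest_target - coords[other].mean(axis=0)
        coords += rng.normal(0.0, jitter_sigma, size=coords.shape)
        frames[f] = coords
        labels.append({"tyr": states[0], "phe": states[1],
                       "category": cat[frozenset(states)]})
    template = peptide.atoms.with_coords(frames[0] if len(schedule) else
                                         peptide.atoms.coords)
    if surface.atoms.cell is not None:
        template.cell = surface.atoms.cell.copy()
        template.pbc = surface.atoms.pbc.copy()
    return AtomTrajectory(template, frames), labels


# ---------------------------------------------------------------------------
# biased reaction-coordinate samples from known potentials


def make_potential(name: str, **params) -> Callable[[float], float]:
    """Analytic 1-D potentials (kcal/mol as a function of angstrom).

    flat
        U = 0 on [lo, hi] (hard walls outside); params lo=0, hi=10.
    harmonic
        U = 0.5 * curvature * (d - d0)^2; params curvature=2.0, d0=5.0.
    morse_like
        U = depth * (1 - exp(-alpha (d - d0)))^2 for d >= d0, and harmonic
        continuation below; plateau value = depth; params depth=5.0,
        alpha=1.0, d0=4.0, with a hard wall at d <= 0.5.
    """
    if name == "flat":
        lo, hi = params.get("lo", 0.0), params.get("hi", 10.0)

        def u(d: float) -> float:
            return 0.0 if lo <= d <= hi else math.inf
    elif name == "harmonic":
        a, d0 = params.get("curvature", 2.0), params.get("d0", 5.0)

        def u(d: float) -> float:
            return 0.5 * a * (d - d0) ** 2
    elif name == "morse_like":
        depth = params.get("depth", 5.0)
        alpha = params.get("alpha", 1.0)
        d0 = params.get("d0", 4.0)

        def u(d: float) -> float:
            if d <= 0.5:
                return math.inf
            return depth * (1.0 - math.exp(-alpha * (d - d0))) ** 2
    else:
        raise ValueError(f"unknown potential {name!r}")
    u.params = dict(params)  # type: ignore[attr-defined]
    u.name = name  # type: ignore[attr-defined]
    return u


def metropolis_sample(u: Callable[[float], float], x0: float, n: int,
                      kt: float, seed: int, burn_in: int = 1000,
                      thin: int = 10) -> Tuple[np.ndarray, float]:
    """1-D Metropolis chain with step size auto-tuned to 30-60% acceptance.

    Every ``thin``-th state is recorded, so the ``n`` returned samples are
    effectively decorrelated. Returns (samples, acceptance_rate); raises
    SamplerError on zero acceptance after tuning.
    """
    rng = np.random.default_rng(seed)
    step = 0.5
    x, ux = float(x0), u(x0)
    if not math.isfinite(ux):
        raise SamplerError("starting point has infinite energy")

    def sweep(m: int, adapt: bool, record_every: int) -> Tuple[np.ndarray, int, int]:
        nonlocal x, ux, step
        out = []
        acc = 0
        batch_acc = 0
        for i in range(m):
            prop = x + step * (2.0 * rng.random() - 1.0)
            uprop = u(prop)
            if uprop <= ux or rng.random() < math.exp(-(uprop - ux) / kt):
                x, ux = prop, uprop
                acc += 1
                batch_acc += 1
            if (i + 1) % record_every == 0:
                out.append(x)
            if adapt and (i + 1) % 100 == 0:
                rate = batch_acc / 100.0
                if rate < 0.30:
                    step *= 0.8
                elif rate > 0.60:
                    step *= 1.25
                batch_acc = 0
        return np.asarray(out), acc, m

    sweep(burn_in, adapt=True, record_every=burn_in + 1)
    samples, accepted, total = sweep(n * thin, adapt=False, record_every=thin)
    if accepted == 0:
        raise SamplerError("Metropolis sampler accepted no moves")
    return samples, accepted / total


def sample_biased_windows(potential: Union[str, Callable[[float], float]],
                          centers: Sequence[float],
                          force_constant: float = DEFAULT_FORCE_CONSTANT,
                          temperature: float = 300.0,
                          n_per_window: int = 5000,
                          seed: int = 0,
                          potential_params: Optional[dict] = None,
                          ) -> Tuple[List[UmbrellaWindow], Dict[float, float]]:
    """Draw umbrella-biased samples of a known potential, one window per
    center (Metropolis under U(d) + 0.5 k (d - center)^2).

    Returns the windows plus a per-center acceptance-rate report. The
    per-window chains are seeded independently from ``seed``.
    """
    u = (make_potential(potential, **(potential_params or {}))
         if isinstance(potential, str) else potential)
    kt = BOLTZMANN_KCAL * temperature
    k_kcal = force_constant / 100.0 / KJ_PER_KCAL
    child_seeds = np.random.SeedSequence(seed).spawn(len(centers))
    windows, report = [], {}
    for c, ss in zip(centers, child_seeds):
        def biased(d: float, _c=float(c)) -> float:
            return u(d) + 0.5 * k_kcal * (d - _c) ** 2

        x0 = float(c)
        if not math.isfinite(u(x0)):  # start inside the domain wall
            x0 = x0 + 1e-3
        samples, rate = metropolis_sample(
            biased, x0, n_per_window, kt,
            seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        windows.append(UmbrellaWindow(center=float(c), samples=samples,
                                      force_constant=force_constant))
        report[float(c)] = rate
    return windows, report


# ---------------------------------------------------------------------------
# hydration shells


def synth_hydration_shell(solute: AtomSet, shell_radius: float = 2.0,
                          shell_sigma: float = 0.2, n: int = 5000,
                          box: Sequence[float] = (30.0, 30.0, 30.0),
                          seed: int = 0, n_background: int = 0) -> AtomSet:
    """Water-oxygen point set: ``n`` points at Gaussian radii about
    ``shell_radius`` around randomly chosen solute atoms, plus
    ``n_background`` uniform points filling the periodic box."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pts = []
    if n > 0:
        which = rng.integers(len(solute.coords), size=n)
        vec = rng.normal(size=(n, 3))
        vec /= np.linalg.norm(vec, axis=1)[:, None]
        radii = rng.normal(shell_radius, shell_sigma, size=n)
        pts.append(solute.coords[which] + radii[:, None] * vec)
    if n_background > 0:
        pts.append(rng.uniform(0.0, 1.0, size=(n_background, 3)) * box)
    coords = np.vstack(pts) if pts else np.empty((0, 3))
    coords = np.mod(coords, box)
    m = len(coords)
    return AtomSet(elements=np.full(m, "O", dtype=object), coords=coords,
                   group_labels=np.full(m, "WAT", dtype=object),
                   cell=np.diag(box), pbc=np.ones(3, dtype=bool))
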