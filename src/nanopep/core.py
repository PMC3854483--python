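"""Shared domain types, physical constants, errors and structure-file I/O.

The package's in-memory currency is the :class:`AtomSet` — a flat,
index-addressed collection of atoms with element symbols, Cartesian
coordinates in angstrom, per-atom group labels (residue tag for peptide
atoms, ``"NANO"`` for nanomaterial atoms) and an optional periodic cell.
Multi-frame data is an :class:`AtomTrajectory`: one topology shared by an
``(n_frames, n_atoms, 3)`` coordinate array.

File I/O (XYZ, PDB, GRO) is delegated to MDAnalysis; GRO coordinates are
converted nm -> angstrom on read by MDAnalysis itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "AtomSet",
    "Ring",
    "AtomTrajectory",
    "ATOMIC_MASSES",
    "VDW_RADII",
    "KJ_PER_KCAL",
    "BOLTZMANN_KCAL",
    "kj_to_kcal",
    "kcal_to_kj",
    "NanopepError",
    "InvalidChiralityError",
    "MalformedLatticeError",
    "ClassificationError",
    "SelectionError",
    "EmptyInputError",
    "GeometryError",
    "ShapeError",
    "RangeError",
    "DegenerateInputError",
    "UnconvergedProfileError",
    "SamplerError",
    "PoseSpecError",
    "SequenceError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]

# ---------------------------------------------------------------------------
# constants

#: thermochemical calorie; exact by definition
KJ_PER_KCAL = 4.184

#: Boltzmann constant in kcal mol^-1 K^-1
BOLTZMANN_KCAL = 0.0019872041

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "NA": 22.98976928,
}

#: Bondi van der Waals radii (angstrom)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "NA": 2.27}


def kj_to_kcal(x):
    """Convert kJ/mol (or kJ mol^-1 length^-2) to kcal-based units."""
    return np.asarray(x, dtype=float) / KJ_PER_KCAL


def kcal_to_kj(x):
    """Inverse of :func:`kj_to_kcal`."""
    return np.asarray(x, dtype=float) * KJ_PER_KCAL


# ---------------------------------------------------------------------------
# errors


class NanopepError(Exception):
    """Base class for all package errors."""


class InvalidChiralityError(NanopepError, ValueError):
    """Chiral index outside the supported armchair family."""


class MalformedLatticeError(NanopepError, ValueError):
    """Bond graph inconsistent with a graphitic lattice (degree > 3)."""


class ClassificationError(NanopepError, ValueError):
    """Stacking classification impossible (e.g. surface without hexagons)."""


class SelectionError(NanopepError, ValueError):
    """An atom/ring selection did not resolve as required."""


class EmptyInputError(NanopepError, ValueError):
    """An operation requiring data received none."""


class GeometryError(NanopepError, ValueError):
    """Geometrically invalid input (e.g. coincident atoms across groups)."""


class ShapeError(NanopepError, ValueError):
    """Mismatched array/atom-count shapes."""


class RangeError(NanopepError, ValueError):
    """A parameter outside its admissible range (e.g. RDF r_max vs cell)."""


class DegenerateInputError(NanopepError, ValueError):
    """Input formally valid but degenerate for the requested statistic."""


class UnconvergedProfileError(NanopepError, RuntimeError):
    """A downstream operation refused an unconverged free-energy profile."""


class SamplerError(NanopepError, RuntimeError):
    """Monte Carlo sampler failed (zero acceptance)."""


class PoseSpecError(NanopepError, ValueError):
    """A synthetic pose specification is inconsistent with its target label."""


class SequenceError(NanopepError, ValueError):
    """Unknown residue letter in a peptide sequence."""


# ---------------------------------------------------------------------------
# domain types


def _as_str_array(values, n: int, default: str) -> np.ndarray:
    if values is None:
        return np.full(n, default, dtype=object)
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise ShapeError(f"expected {n} per-atom labels, got shape {arr.shape}")
    return arr


@dataclass
class AtomSet:
    """Named atoms with elements, coordinates (angstrom) and group labels.

    Atom ids are implicit, contiguous 0-based indices into the arrays.
    ``cell`` holds three lattice vectors (rows, angstrom); ``pbc`` flags
    per-axis periodicity. Only diagonal (orthorhombic) periodic cells are
    supported by the minimum-image helpers.
    """

    elements: np.ndarray
    coords: np.ndarray
    group_labels: np.ndarray = None  # type: ignore[assignment]
    names: Optional[np.ndarray] = None
    cell: Optional[np.ndarray] = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.elements = _as_str_array(self.elements, n, "C")
        self.group_labels = _as_str_array(self.group_labels, n, "UNK")
        if self.names is not None:
            self.names = _as_str_array(self.names, n, "X")
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
            if self.pbc.any() and abs(np.linalg.det(self.cell)) < 1e-9:
                raise GeometryError("degenerate periodic cell")

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    @property
    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[e.upper()] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - unusual elements
            raise KeyError(f"no mass tabulated for element {exc}") from exc

    def center_of_mass(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        idx = np.asarray(indices) if indices is not None else self.atom_ids
        m = self.masses[idx]
        return (self.coords[idx] * m[:, None]).sum(axis=0) / m.sum()

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    # -- derived sets ------------------------------------------------------

    def select(self, indices: Sequence[int]) -> "AtomSet":
        idx = np.asarray(indices, dtype=int)
        return AtomSet(
            elements=self.elements[idx].copy(),
            coords=self.coords[idx].copy(),
            group_labels=self.group_labels[idx].copy(),
            names=None if self.names is None else self.names[idx].copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        out = self.select(self.atom_ids)
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(out.coords) != self.n_atoms:
            raise ShapeError("coordinate array does not match atom count")
        return out

    def transformed(self, rotation: Optional[np.ndarray] = None,
                    translation: Optional[np.ndarray] = None) -> "AtomSet":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return self.with_coords(xyz)

    @staticmethod
    def concatenate(parts: Sequence["AtomSet"]) -> "AtomSet":
        if not parts:
            raise EmptyInputError("nothing to concatenate")
        cell = next((p.cell for p in parts if p.cell is not None), None)
        pbc = next((p.pbc for p in parts if p.pbc.any()), parts[0].pbc)
        names = None
        if all(p.names is not None for p in parts):
            names = np.concatenate([p.names for p in parts])
        return AtomSet(
            elements=np.concatenate([p.elements for p in parts]),
            coords=np.vstack([p.coords for p in parts]),
            group_labels=np.concatenate([p.group_labels for p in parts]),
            names=names,
            cell=cell,
            pbc=pbc,
        )

    # -- periodicity -------------------------------------------------------

    @property
    def box_lengths(self) -> Optional[np.ndarray]:
        """Diagonal cell edge lengths; raises for periodic non-diagonal cells."""
        if self.cell is None:
            return None
        off = self.cell - np.diag(np.diag(self.cell))
        if self.pbc.any() and np.abs(off).max() > 1e-9:
            raise GeometryError("only orthorhombic periodic cells are supported")
        return np.diag(self.cell).copy()

    def minimum_image(self, dvecs: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention along periodic axes."""
        d = np.asarray(dvecs, dtype=float)
        if self.cell is None or not self.pbc.any():
            return d
        lengths = self.box_lengths
        d = d.copy()
        for ax in range(3):
            if self.pbc[ax] and lengths[ax] > 0:
                d[..., ax] -= lengths[ax] * np.round(d[..., ax] / lengths[ax])
        return d


@dataclass(frozen=True)
class Ring:
    """A perceived 5- or 6-membered ring: ordered members, centroid, unit normal."""

    member_ids: tuple
    centroid: np.ndarray
    normal: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise GeometryError("ring normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        if self.size not in (5, 6):
            raise GeometryError("rings must have 5 or 6 members")


class AtomTrajectory:
    """Ordered frames sharing one topology.

    Parameters
    ----------
    template
        AtomSet defining elements/labels/cell for every frame.
    coords
        ``(n_frames, n_atoms, 3)`` array, angstrom.
    timestep_label
        Free-text tag for the frame spacing (carried through, not parsed).
    """

    def __init__(self, template: AtomSet, coords: np.ndarray,
                 timestep_label: Optional[str] = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[1] != template.n_atoms:
            raise ShapeError(
                f"coords shape {coords.shape} does not match template "
                f"({template.n_atoms} atoms)")
        self.template = template
        self.coords = coords
        self.timestep_label = timestep_label

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def n_atoms(self) -> int:
        return self.template.n_atoms

    def frame(self, i: int) -> AtomSet:
        return self.template.with_coords(self.coords[i])

    def __iter__(self) -> Iterator[AtomSet]:
        for i in range(len(self)):
            yield self.frame(i)

    @property
    def residues(self) -> "list[tuple[str, np.ndarray]]":
        """Ordered (label, atom-index array) pairs for non-NANO groups.

        Residues partition the peptide atoms; the nanomaterial ("NANO")
        group is excluded.
        """
        labels = self.template.group_labels
        out, seen = [], {}
        for i, lab in enumerate(labels):
            if lab == "NANO":
                continue
            if lab not in seen:
                seen[lab] = []
                out.append(lab)
            seen[lab].append(i)
        return [(lab, np.asarray(seen[lab], dtype=int)) for lab in out]

    def peptide_indices(self) -> np.ndarray:
        return np.flatnonzero(self.template.group_labels != "NANO")

    def surface_indices(self) -> np.ndarray:
        return np.flatnonzero(self.template.group_labels == "NANO")


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis-backed)

_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d*)$")


def _split_label(label: str) -> "tuple[str, int]":
    m = _LABEL_RE.match(label)
    if m and m.group(2):
        return m.group(1)[:4], int(m.group(2))
    return label[:4] or "UNK", 1


def _to_universe(atoms: AtomSet, coords3d: Optional[np.ndarray] = None):
    import MDAnalysis as mda

    labels = [_split_label(l) for l in atoms.group_labels]
    uniq: "list[tuple[str, int]]" = []
    resindex = np.empty(atoms.n_atoms, dtype=int)
    for i, key in enumerate(labels):
        if not uniq or uniq[-1] != key:
            uniq.append(key)
        resindex[i] = len(uniq) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            atoms.n_atoms, n_residues=len(uniq), atom_resindex=resindex,
            residue_segindex=np.zeros(len(uniq), dtype=int), trajectory=True)
        names = atoms.names if atoms.names is not None else atoms.elements
        u.add_TopologyAttr("names", [str(x) for x in names])
        u.add_TopologyAttr("elements", [str(e) for e in atoms.elements])
        u.add_TopologyAttr("resnames", [r for r, _ in uniq])
        u.add_TopologyAttr("resids", [i for _, i in uniq])
        u.add_TopologyAttr(
            "record_types",
            ["HETATM" if l == "NANO" else "ATOM" for l in atoms.group_labels])
        u.atoms.positions = atoms.coords
        if atoms.cell is not None:
            lengths = atoms.box_lengths
            u.dimensions = [max(lengths[0], 1.0), max(lengths[1], 1.0),
                            max(lengths[2], 1.0), 90.0, 90.0, 90.0]
        if coords3d is not None:
            u.load_new(np.asarray(coords3d, dtype=float), format="memory")
    return u


def _from_universe(u, cell: Optional[np.ndarray] = None) -> AtomSet:
    n = len(u.atoms)
    if hasattr(u.atoms, "elements") and all(u.atoms.elements):
        elements = [str(e).capitalize() for e in u.atoms.elements]
    else:
        elements = [str(nm)[0].upper() for nm in u.atoms.names]
    labels = []
    for a in u.atoms:
        try:
            resname, resid = str(a.resname), int(a.resid)
        except Exception:
            resname, resid = "UNK", 1
        labels.append("NANO" if resname.upper().startswith("NANO")
                      else f"{resname}{resid}")
    names = [str(nm) for nm in u.atoms.names] if hasattr(u.atoms, "names") else None
    if cell is None and u.dimensions is not None and u.dimensions[:3].max() > 0:
        cell = np.diag(u.dimensions[:3].astype(float))
    return AtomSet(elements=np.asarray(elements, dtype=object),
                   coords=u.atoms.positions.astype(float),
                   group_labels=np.asarray(labels, dtype=object),
                   names=None if names is None else np.asarray(names, dtype=object),
                   cell=cell,
                   pbc=np.zeros(3, dtype=bool) if cell is None
                   else np.ones(3, dtype=bool))


def write_structure(atoms: AtomSet, path: str) -> None:
    """Write a single-frame structure; format chosen from the extension
    (.xyz, .pdb, .gro)."""
    u = _to_universe(atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_structure(path: str) -> AtomSet:
    """Read a single-frame XYZ/PDB/GRO structure into an AtomSet
    (GRO nm -> angstrom conversion handled by MDAnalysis)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return _from_universe(u)


def write_trajectory(traj: AtomTrajectory, path: str) -> None:
    """Write a multi-frame trajectory (multi-frame XYZ or multi-model PDB)."""
    import MDAnalysis as mda

    u = _to_universe(traj.template, coords3d=traj.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def read_trajectory(path: str, template: Optional[AtomSet] = None) -> AtomTrajectory:
    """Read a multi-frame XYZ/PDB file; an optional template supplies group
    labels and cell when the file format does not carry them (XYZ)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
    if template is None:
        template = _from_universe(u)
    if template.n_atoms != coords.shape[1]:
        raise ShapeError("template does not match trajectory atom count")
    return AtomTrajectory(template, coords)
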