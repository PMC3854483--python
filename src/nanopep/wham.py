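"""Umbrella sampling reaction coordinate, WHAM, and binding-energy arithmetic.

The reaction coordinate is the separation between the nanomaterial's
center of mass and the glycine alpha-carbon of the peptide. Biased
per-window samples of that coordinate (harmonic umbrella restraints,
default force constant 8000 kJ mol^-1 nm^-2, windows every 0.5 angstrom)
are combined by the weighted histogram analysis method (WHAM) into one
unbiased potential of mean force, zeroed at the bound-state minimum; the
dissociation free energy is the mean of the final plateau of that curve.

All free energies are in kcal/mol; distances in angstrom; the restraint
constant is stored in the conventional kJ mol^-1 nm^-2 and converted
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .core import (
    AtomSet,
    BOLTZMANN_KCAL,
    EmptyInputError,
    KJ_PER_KCAL,
    SelectionError,
    UnconvergedProfileError,
)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "EnergyTriple",
    "reaction_coordinate",
    "wham_solve",
    "window_overlap",
    "dissociation_free_energy",
    "binding_energy",
    "write_window_files",
    "read_window_files",
]

#: default umbrella force constant, kJ mol^-1 nm^-2
DEFAULT_FORCE_CONSTANT = 8000.0


@dataclass
class UmbrellaWindow:
    """One biased window: restraint center (angstrom), harmonic force
    constant (kJ mol^-1 nm^-2) and the sampled reaction-coordinate values."""

    center: float
    samples: np.ndarray
    force_constant: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.samples.size < 1:
            raise EmptyInputError("umbrella window has no samples")

    @property
    def k_kcal_per_A2(self) -> float:
        """Force constant in kcal mol^-1 angstrom^-2 (1 nm^2 = 100 A^2)."""
        return self.force_constant / 100.0 / KJ_PER_KCAL

    def bias_energy(self, x) -> np.ndarray:
        """Restraint energy at coordinate x, kcal/mol."""
        return 0.5 * self.k_kcal_per_A2 * (np.asarray(x, float) - self.center) ** 2


@dataclass
class PMFProfile:
    """Unbiased free-energy profile, zeroed at its minimum (kcal/mol)."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    converged: bool
    iterations: int
    temperature: float = 300.0
    overlap_ok: bool = True
    overlaps: Optional[np.ndarray] = field(default=None, repr=False)


def reaction_coordinate(frame: AtomSet, surface_ids: Sequence[int],
                        gly_ca_id: int) -> float:
    """Distance (angstrom) from the mass-weighted surface center of mass
    to the glycine alpha-carbon atom."""
    surf = np.asarray(surface_ids, dtype=int)
    if surf.size == 0:
        raise SelectionError("no surface atoms selected")
    if gly_ca_id is None or not (0 <= int(gly_ca_id) < frame.n_atoms):
        raise SelectionError("glycine alpha-carbon id does not resolve")
    com = frame.center_of_mass(surf)
    return float(np.linalg.norm(frame.coords[int(gly_ca_id)] - com))


def _common_edges(windows: Sequence[UmbrellaWindow], bin_width: float) -> np.ndarray:
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    lo = np.floor(lo / bin_width) * bin_width
    n = int(np.ceil((hi - lo) / bin_width + 1e-9)) + 1
    return lo + bin_width * np.arange(n + 1)


def window_overlap(windows: Sequence[UmbrellaWindow],
                   bin_width: float = 0.1) -> np.ndarray:
    """Histogram intersection fraction for each adjacent window pair.

    Windows are taken in order of increasing center; each value is
    sum_b min(p_i(b), p_{i+1}(b)) of the normalized histograms, in [0, 1].
    """
    if len(windows) < 2:
        raise EmptyInputError("window_overlap requires at least two windows")
    ordered = sorted(windows, key=lambda w: w.center)
    edges = _common_edges(ordered, bin_width)
    hists = [np.histogram(w.samples, bins=edges)[0] / w.samples.size
             for w in ordered]
    return np.array([np.minimum(hists[i], hists[i + 1]).sum()
                     for i in range(len(hists) - 1)])


def wham_solve(windows: Sequence[UmbrellaWindow], bin_width: float = 0.1,
               temperature: float = 300.0, tol: float = 1e-7,
               max_iter: int = 100_000) -> PMFProfile:
    """Self-consistent WHAM solution of the unbiased PMF.

    Iterates the window free-energy constants until the largest change
    falls below ``tol`` (kcal/mol). A single window degenerates to direct
    Boltzmann inversion of its (possibly unbiased) histogram. Adjacent
    windows with zero histogram overlap trigger a warning and flag the
    profile; non-convergence is flagged, not raised.
    """
    if len(windows) == 0:
        raise EmptyInputError("wham_solve requires at least one window")
    ordered = sorted(windows, key=lambda w: w.center)
    overlaps = None
    overlap_ok = True
    if len(ordered) >= 2:
        overlaps = window_overlap(ordered, bin_width)
        if np.any(overlaps <= 0.0):
            overlap_ok = False
            warnings.warn("adjacent umbrella windows have zero histogram "
                          "overlap; PMF may be disconnected", stacklevel=2)

    kt = BOLTZMANN_KCAL * temperature
    beta = 1.0 / kt
    edges = _common_edges(ordered, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.array([np.histogram(w.samples, bins=edges)[0] for w in ordered],
                    dtype=float)
    n_i = hist.sum(axis=1)
    total = hist.sum(axis=0)
    populated = total > 0
    # Boltzmann factor of the harmonic bias averaged analytically over each
    # bin (erf integral); the stiff default restraint varies by several kT
    # across one bin, so evaluating it only at bin centers would bias f_i
    from scipy.special import erf

    log_c = np.empty((len(ordered), len(centers)))
    for i, w in enumerate(ordered):
        s = np.sqrt(beta * w.k_kcal_per_A2 / 2.0)
        if s * bin_width < 1e-8:  # negligible bias: avoid 0/0
            log_c[i] = -beta * w.bias_energy(centers)
            continue
        num = erf(s * (edges[1:] - w.center)) - erf(s * (edges[:-1] - w.center))
        mean_weight = num * np.sqrt(np.pi) / (2.0 * s * bin_width)
        log_c[i] = np.log(np.maximum(mean_weight, 1e-300))

    f = np.zeros(len(ordered))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # p_b ~ total_b / sum_i N_i exp(beta f_i) exp(-beta w_ib)
        log_denom = np.logaddexp.reduce(
            np.log(n_i)[:, None] + beta * f[:, None] + log_c, axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(populated, np.log(total) - log_denom, -np.inf)
        # f_i = -kT ln sum_b exp(-beta w_ib) p_b
        f_new = -kt * np.logaddexp.reduce(log_c[:, populated]
                                          + log_p[None, populated], axis=1)
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break

    log_denom = np.logaddexp.reduce(
        np.log(n_i)[:, None] + beta * f[:, None] + log_c, axis=0)
    with np.errstate(divide="ignore"):
        log_p = np.log(total[populated]) - log_denom[populated]
    pmf = -kt * log_p
    pmf -= pmf.min()
    return PMFProfile(bin_centers=centers[populated], free_energy=pmf,
                      converged=converged, iterations=it,
                      temperature=temperature, overlap_ok=overlap_ok,
                      overlaps=overlaps)


def dissociation_free_energy(pmf: PMFProfile, plateau_span: float = 2.0) -> float:
    """Dissociation free energy: mean PMF over the final ``plateau_span``
    angstrom of the profile (the large-separation plateau), relative to
    the bound-state minimum at zero. Refuses unconverged profiles."""
    if not pmf.converged:
        raise UnconvergedProfileError(
            "refusing to integrate an unconverged PMF")
    hi = pmf.bin_centers.max()
    mask = pmf.bin_centers >= hi - plateau_span + 1e-9
    if not mask.any():
        raise EmptyInputError("no populated bins in the plateau span")
    return float(pmf.free_energy[mask].mean())


def write_window_files(windows: Sequence[UmbrellaWindow], directory) -> None:
    """Write each window as ``window_<center>.dat``: one plain-text column
    of reaction-coordinate samples (angstrom)."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for w in windows:
        np.savetxt(d / f"window_{w.center:g}.dat", w.samples, fmt="%.6f")


def read_window_files(directory,
                      force_constant: float = DEFAULT_FORCE_CONSTANT,
                      ) -> List[UmbrellaWindow]:
    """Read ``window_<center>.dat`` files back into umbrella windows;
    restraint metadata (force constant) comes from the caller's config."""
    from pathlib import Path

    files = sorted(Path(directory).glob("window_*.dat"),
                   key=lambda p: float(p.stem.split("_", 1)[1]))
    if not files:
        raise EmptyInputError(f"no window_*.dat files under {directory}")
    return [UmbrellaWindow(center=float(p.stem.split("_", 1)[1]),
                           samples=np.loadtxt(p),
                           force_constant=force_constant)
            for p in files]


@dataclass(frozen=True)
class EnergyTriple:
    """Total energies of the complex and its isolated parts (one unit system)."""

    e_complex: float
    e_peptide: float
    e_nanomaterial: float


def binding_energy(e: EnergyTriple) -> float:
    """Binding energy of the adsorbed peptide:
    E_b = E(complex) - E(peptide) - E(nanomaterial)."""
    return e.e_complex - e.e_peptide - e.e_nanomaterial
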