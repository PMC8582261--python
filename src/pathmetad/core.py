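"""Structure/trajectory data model, superposition and displacement metrics.

Coordinates are stored in angstrom throughout the package; energies are
kJ/mol internally (kcal/mol = kJ/mol / 4.184 for reporting).  The mean
squared displacement convention is **per-atom** (units A^2), so the path-CV
smoothing parameter lambda carries units of A^-2; see :mod:`pathmetad.pathcv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._linalg import check_fit_points, fitted_msd
from .errors import DimensionError, SelectionError

KJ_PER_KCAL = 4.184
#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083145


def _as_str_array(values, n: int, default: str) -> np.ndarray:
    if values is None:
        return np.full(n, default, dtype=object)
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise DimensionError(f"metadata array length {arr.shape} != atom count {n}")
    return arr


@dataclass
class Structure:
    """A single molecular configuration with per-atom metadata.

    Parameters
    ----------
    coords
        (n_atoms, 3) cartesian coordinates in angstrom; must be finite.
    atom_names, residue_names, elements, chain_ids
        Per-atom text labels; default to CA/ALA/C/A for toy systems.
    residue_ids
        Per-atom integer residue numbers; default 1..n.
    """

    coords: np.ndarray
    atom_names: np.ndarray = None
    residue_ids: np.ndarray = None
    residue_names: np.ndarray = None
    elements: np.ndarray = None
    chain_ids: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DimensionError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[0]
        self.atom_names = _as_str_array(self.atom_names, n, "CA")
        self.residue_names = _as_str_array(self.residue_names, n, "ALA")
        self.elements = _as_str_array(self.elements, n, "C")
        self.chain_ids = _as_str_array(self.chain_ids, n, "A")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, n + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.residue_ids.shape != (n,):
            raise DimensionError("residue_ids length mismatch")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure":
        return Structure(
            self.coords.copy(),
            self.atom_names.copy(),
            self.residue_ids.copy(),
            self.residue_names.copy(),
            self.elements.copy(),
            self.chain_ids.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same metadata, new coordinates."""
        return Structure(
            np.asarray(coords, dtype=float),
            self.atom_names,
            self.residue_ids,
            self.residue_names,
            self.elements,
            self.chain_ids,
        )

    def subset(self, selection: "AtomSelection") -> "Structure":
        idx = selection.validate(self.n_atoms)
        return Structure(
            self.coords[idx],
            self.atom_names[idx],
            self.residue_ids[idx],
            self.residue_names[idx],
            self.elements[idx],
            self.chain_ids[idx],
        )


@dataclass
class AtomSelection:
    """An ordered list of atom indices with a human-readable label."""

    indices: np.ndarray
    label: str = "selection"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise SelectionError("selection indices must be 1-D")
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError(f"selection '{self.label}' has duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, n_atoms: int) -> np.ndarray:
        if len(self.indices) == 0:
            raise SelectionError(f"selection '{self.label}' is empty")
        if self.indices.min() < 0 or self.indices.max() >= n_atoms:
            raise SelectionError(
                f"selection '{self.label}' out of bounds for {n_atoms} atoms"
            )
        return self.indices


def select_all(structure: Structure) -> AtomSelection:
    return AtomSelection(np.arange(structure.n_atoms), "all")


def select_calpha(structure: Structure) -> AtomSelection:
    idx = np.flatnonzero(structure.atom_names == "CA")
    return AtomSelection(idx, "calpha")


def select_heavy(structure: Structure) -> AtomSelection:
    idx = np.flatnonzero(structure.elements != "H")
    return AtomSelection(idx, "heavy")


def select_residues(structure: Structure, residue_ids: Sequence[int], label: str = "residues") -> AtomSelection:
    mask = np.isin(structure.residue_ids, np.asarray(residue_ids, dtype=int))
    return AtomSelection(np.flatnonzero(mask), label)


class Trajectory:
    """An ordered sequence of frames sharing one atom layout.

    Stored as a (n_frames, n_atoms, 3) coordinate array plus the metadata of
    a template :class:`Structure`; optional per-frame times in ps.
    """

    def __init__(self, frames, times: np.ndarray | None = None):
        if isinstance(frames, np.ndarray):
            raise TypeError("build Trajectory from Structures or use from_coords")
        frames = list(frames)
        if len(frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].n_atoms
        for i, f in enumerate(frames):
            if f.n_atoms != n:
                raise DimensionError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n}"
                )
        self.template = frames[0]
        self.coords = np.stack([f.coords for f in frames])
        self.times = None if times is None else np.asarray(times, dtype=float)
        if self.times is not None and len(self.times) != len(frames):
            raise DimensionError("times length != frame count")

    @classmethod
    def from_coords(cls, coords: np.ndarray, template: Structure, times=None) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (template.n_atoms, 3):
            raise DimensionError(
                f"coords must be (n_frames, {template.n_atoms}, 3), got {coords.shape}"
            )
        obj = cls.__new__(cls)
        obj.template = template
        obj.coords = coords
        obj.times = None if times is None else np.asarray(times, dtype=float)
        if obj.times is not None and len(obj.times) != len(coords):
            raise DimensionError("times length != frame count")
        return obj

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.template.with_coords(self.coords[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(len(self)):
            yield self.frame(i)


def superpose_kabsch(
    mobile: Structure, reference: Structure, fit: AtomSelection
) -> tuple[Structure, np.ndarray, float]:
    """Optimally superpose ``mobile`` onto ``reference`` over the fit atoms.

    Returns ``(aligned, rotation, rmsd)``: ``aligned`` applies the optimal
    rigid transform (determined on the fit atoms) to *all* atoms of
    ``mobile``; ``rotation`` is the 3x3 proper rotation; ``rmsd`` (A) is the
    least-squares minimum over the fit atoms.

    Raises
    ------
    DegenerateFitError
        If fewer than 3 fit atoms are given or they are collinear.
    """
    idx_m = fit.validate(mobile.n_atoms)
    fit.validate(reference.n_atoms)
    P = mobile.coords[idx_m]
    Q = reference.coords[fit.indices]
    check_fit_points(P)
    check_fit_points(Q)
    msd, R = fitted_msd(P, Q)
    cm, cq = P.mean(axis=0), Q.mean(axis=0)
    aligned_coords = (mobile.coords - cm) @ R.T + cq
    return mobile.with_coords(aligned_coords), R, float(np.sqrt(msd))


def displacement_metrics(
    a: Structure, b: Structure, selection: AtomSelection, fit: bool = False
) -> tuple[float, float]:
    """RMSD (A) and per-atom MSD (A^2) between two structures over a selection.

    With ``fit=True`` the selection atoms are optimally superposed first
    (Kabsch); otherwise displacements are taken in the given frames.
    """
    ia = selection.validate(a.n_atoms)
    ib = selection.validate(b.n_atoms)
    if len(ia) != len(ib):
        raise DimensionError("selection resolves to different sizes in a and b")
    P, Q = a.coords[ia], b.coords[ib]
    if fit:
        msd, _ = fitted_msd(P, Q)
    else:
        d = P - Q
        msd = float((d * d).sum() / len(P))
    return float(np.sqrt(msd)), float(msd)
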