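"""Structural observables along paths and trajectories.

Per-element RMSD traces (fit on the element, RMSD over the element),
hydrogen-bond counts (distance + angle criterion), Shrake-Rupley SASA,
backbone phi/psi dihedrals (IUPAC sign convention) and pairwise RMSD maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atan2, degrees

import numpy as np
from scipy.spatial import cKDTree

from ._linalg import fitted_msd, fitted_msd_batch
from .core import AtomSelection, Structure, Trajectory
from .errors import DimensionError, RadiusTableError, SelectionError, TopologyError

__all__ = [
    "ElementDefinition",
    "element_rmsd_trace",
    "hbond_count",
    "sasa_shrake_rupley",
    "backbone_dihedrals",
    "BackboneDihedrals",
    "pairwise_rmsd_map",
    "VDW_RADII",
]

#: Bondi (1964) van der Waals radii, A
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Na": 2.27, "K": 2.75, "Mg": 1.73, "Zn": 1.39, "Fe": 1.95,
}


@dataclass
class ElementDefinition:
    """A named structural element given by residue-id ranges.

    ``residues`` is a list of (lo, hi) inclusive ranges, e.g. the A-loop or
    the alphaC helix of a kinase supplied from a user config.
    """

    name: str
    residues: list

    def resolve(self, structure: Structure, mode: str = "calpha") -> AtomSelection:
        mask = np.zeros(structure.n_atoms, dtype=bool)
        for lo, hi in self.residues:
            mask |= (structure.residue_ids >= lo) & (structure.residue_ids <= hi)
        if mode == "calpha":
            mask &= structure.atom_names == "CA"
        elif mode == "heavy":
            mask &= structure.elements != "H"
        else:
            raise SelectionError(f"unknown mode '{mode}'")
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise SelectionError(f"element '{self.name}' resolves to no atoms")
        return AtomSelection(idx, self.name)


def element_rmsd_trace(
    traj: Trajectory, reference: Structure, element: ElementDefinition, mode: str = "calpha"
) -> np.ndarray:
    """Per-frame fitted RMSD (A) of one structural element vs a reference.

    Each frame is superposed on the reference using only the element's atoms
    (calpha or heavy), and the RMSD is computed over those same atoms — the
    convention used to trace e.g. A-loop opening along an activation path.
    """
    sel = element.resolve(reference, mode)
    sel.validate(traj.n_atoms)
    ref = reference.coords[sel.indices]
    msd, _ = fitted_msd_batch(ref, traj.coords[:, sel.indices, :])
    return np.sqrt(msd)


def _attached_hydrogens(structure: Structure, donor_idx: np.ndarray, d_dh: float = 1.25):
    h_idx = np.flatnonzero(structure.elements == "H")
    out = {}
    for d in donor_idx:
        if len(h_idx) == 0:
            attached = []
        else:
            dist = np.linalg.norm(structure.coords[h_idx] - structure.coords[d], axis=1)
            attached = h_idx[dist <= d_dh].tolist()
        if not attached:
            raise TopologyError(f"donor atom {d} has no attached hydrogen within {d_dh} A")
        out[int(d)] = attached
    return out


def hbond_count(
    structure: Structure,
    donors: AtomSelection,
    acceptors: AtomSelection,
    d_max: float = 0.35,
    angle_max: float = 30.0,
) -> int:
    """Count donor-acceptor pairs satisfying the geometric H-bond criterion.

    A pair counts when the donor-acceptor distance is <= ``d_max`` (nm) and
    the hydrogen-donor-acceptor angle of any hydrogen attached to the donor
    is <= ``angle_max`` degrees (0.35 nm / 30 deg defaults).
    """
    di = donors.validate(structure.n_atoms)
    ai = acceptors.validate(structure.n_atoms)
    hydro = _attached_hydrogens(structure, di)
    d_max_ang = d_max * 10.0
    count = 0
    for d in di:
        for a in ai:
            if a == d:
                continue
            r = structure.coords[a] - structure.coords[d]
            dist = np.linalg.norm(r)
            if dist > d_max_ang or dist == 0.0:
                continue
            for h in hydro[int(d)]:
                hv = structure.coords[h] - structure.coords[d]
                ca = np.dot(hv, r) / (np.linalg.norm(hv) * dist)
                ang = degrees(np.arccos(np.clip(ca, -1.0, 1.0)))
                if ang <= angle_max:
                    count += 1
                    break
    return count


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa_shrake_rupley(
    structure: Structure,
    selection: AtomSelection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2) of a selection.

    Dot-sphere construction: ``n_points`` points on each selected atom's
    expanded sphere (vdW radius + probe); a point is buried when inside any
    other atom's expanded sphere.  The selection is evaluated in the context
    of the full structure.  Radii come from the bundled Bondi table.
    """
    if selection is None:
        selection = AtomSelection(np.arange(structure.n_atoms), "all")
    idx = selection.validate(structure.n_atoms)
    try:
        radii = np.array([VDW_RADII[str(e)] for e in structure.elements])
    except KeyError as exc:
        raise RadiusTableError(f"no van der Waals radius for element {exc}") from None
    pts = _sphere_points(n_points)
    coords = structure.coords
    tree = cKDTree(coords)
    r_exp = radii + probe
    max_reach = r_exp.max()
    total = 0.0
    for i in idx:
        sphere = coords[i] + r_exp[i] * pts
        neigh = [j for j in tree.query_ball_point(coords[i], r_exp[i] + max_reach) if j != i]
        if neigh:
            d = np.linalg.norm(sphere[:, None, :] - coords[neigh][None, :, :], axis=2)
            # ties (points exactly on a neighbour's expanded sphere, as for
            # coincident atoms) are broken by atom order: the lower index wins
            strict = d < r_exp[neigh][None, :] - 1e-9
            tie = (np.abs(d - r_exp[neigh][None, :]) <= 1e-9) & (np.asarray(neigh) < i)[None, :]
            buried = (strict | tie).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * r_exp[i] ** 2 * frac
    return float(total)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (deg, IUPAC right-handed convention), range (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = float(v @ w)
    y = float(np.cross(b1, v) @ w)
    ang = degrees(atan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else ang


@dataclass
class BackboneDihedrals:
    """phi/psi for one residue; NaN marks an undefined (chain-terminal) angle."""

    phi: float
    psi: float

    @property
    def phi_defined(self) -> bool:
        return np.isfinite(self.phi)

    @property
    def psi_defined(self) -> bool:
        return np.isfinite(self.psi)


def _find_atom(structure: Structure, res_id: int, name: str):
    hits = np.flatnonzero(
        (structure.residue_ids == res_id) & (structure.atom_names == name)
    )
    return int(hits[0]) if len(hits) else None


def backbone_dihedrals(structure: Structure, residue: int) -> BackboneDihedrals:
    """phi = C(i-1)-N-CA-C and psi = N-CA-C-N(i+1) for residue ``residue``.

    Chain-terminal residues get NaN for the undefined angle (flag, not an
    exception); a residue missing its own N/CA/C raises TopologyError.
    """
    n = _find_atom(structure, residue, "N")
    ca = _find_atom(structure, residue, "CA")
    c = _find_atom(structure, residue, "C")
    if n is None or ca is None or c is None:
        raise TopologyError(f"residue {residue} lacks N/CA/C backbone atoms")
    c_prev = _find_atom(structure, residue - 1, "C")
    n_next = _find_atom(structure, residue + 1, "N")
    x = structure.coords
    phi = dihedral_angle(x[c_prev], x[n], x[ca], x[c]) if c_prev is not None else float("nan")
    psi = dihedral_angle(x[n], x[ca], x[c], x[n_next]) if n_next is not None else float("nan")
    return BackboneDihedrals(phi=phi, psi=psi)


def pairwise_rmsd_map(
    set_a: Trajectory, set_b: Trajectory, selection: AtomSelection
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted-RMSD matrix between two frame sets over a selection.

    Returns ``(matrix, row_argmin)`` with ``matrix[i, j]`` the fitted RMSD
    of a_i vs b_j (A) and ``row_argmin[i]`` the closest b frame per a frame.
    """
    ia = selection.validate(set_a.n_atoms)
    ib = selection.validate(set_b.n_atoms)
    if len(ia) != len(ib):
        raise DimensionError("selection resolves to different sizes in the two sets")
    A = set_a.coords[:, ia, :]
    B = set_b.coords[:, ib, :]
    out = np.empty((len(A), len(B)))
    for i in range(len(A)):
        msd, _ = fitted_msd_batch(A[i], B)
        out[i] = np.sqrt(msd)
    return out, np.argmin(out, axis=1)
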