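"""Path collective variables s(R), s_hat(R), z(R) over a reference path.

Given N ordered reference frames X_1..X_N (C-alpha coordinates) and the
per-atom mean squared displacement d_j^2(X) = MSD(X, X_j) after optimal
superposition, the progress variable and the distance from the path are

    s(R) = sum_j j exp(-lambda d_j^2) / sum_j exp(-lambda d_j^2)
    z(R) = -(1/lambda) ln sum_j exp(-lambda d_j^2)

with j = 1..N, and the normalized progress s_hat = (s - 1)/(N - 1) in
[0, 1] so paths with different frame counts are comparable.  The smoothing
parameter is tied to the path resolution,

    lambda = 2.3 / <MSD between consecutive frames>,

which for ~0.5 A frame spacing gives lambda ~ 9.2 A^-2, the regime used for
kinase activation paths.  MSD is **per-atom** (A^2) so lambda carries A^-2.

Evaluation uses a numerically stable log-sum-exp and aligns the probe to
every path frame independently ("after optimal alignment").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from ._linalg import fitted_msd_batch
from .core import AtomSelection, Structure, Trajectory
from .errors import (
    DegeneratePathError,
    DimensionError,
    ParameterError,
    PathGapError,
)

__all__ = [
    "ReferencePath",
    "PathCVValue",
    "PathValidationReport",
    "select_frames",
    "validate_path",
    "compute_lambda",
    "evaluate_path_cvs",
    "path_cv_gradients",
    "smooth_trajectory",
]


def smooth_trajectory(traj: Trajectory, window: int) -> Trajectory:
    """Boxcar-average trajectory coordinates over ``window`` frames.

    Path frames are selected from the *mean drift* of a transition
    trajectory rather than its raw thermal jitter: frame selection from an
    unsmoothed finely-saved trajectory yields a path that folds back on
    itself inside the thermal cloud, making index-distant frames spatially
    close and the progress variable s ill-conditioned.  (Production
    protocols achieve the same implicitly by saving coordinates at a coarse
    interval.)
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window == 1:
        return traj
    flat = traj.coords.reshape(len(traj), -1)
    kernel = np.ones(window) / window
    sm = np.apply_along_axis(lambda m: np.convolve(m, kernel, mode="valid"), 0, flat)
    return Trajectory.from_coords(sm.reshape(-1, traj.n_atoms, 3), traj.template)


@dataclass
class ReferencePath:
    """N ordered reference frames with the smoothing parameter lambda.

    ``frames``: (N, M, 3) coordinates of the selection atoms (A);
    ``lam``: smoothing parameter (A^-2); ``spacing``: the N-1 consecutive
    fitted RMSDs (A); ``selection``: indices of the path atoms in the parent
    structure.
    """

    frames: np.ndarray
    lam: float
    spacing: np.ndarray
    selection: AtomSelection

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) < 2:
            raise ParameterError("a reference path needs >= 2 frames of (M, 3) coords")
        if self.lam <= 0:
            raise ParameterError("lambda must be > 0")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if len(self.spacing) != len(self.frames) - 1:
            raise DimensionError("spacing must have N-1 entries")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def _centred(self):
        """Cached centred frames and their squared norms (evaluation hot path)."""
        if getattr(self, "_fc", None) is None or len(self._fc) != len(self.frames):
            self._fc = self.frames - self.frames.mean(axis=1, keepdims=True)
            self._fc2 = (self._fc * self._fc).sum(axis=(1, 2))
        return self._fc, self._fc2

    @classmethod
    def from_frames(
        cls,
        frames: np.ndarray,
        selection: AtomSelection,
        lam: float | None = None,
    ) -> "ReferencePath":
        """Build a path from raw frame coordinates; lambda defaults to 2.3/<MSD>."""
        frames = np.asarray(frames, dtype=float)
        spacing = _consecutive_rmsd(frames)
        path = cls(frames, lam if lam is not None else 1.0, spacing, selection)
        if lam is None:
            path.lam = compute_lambda(path)
        return path

    def to_trajectory(self, template: Structure) -> Trajectory:
        """Expand path frames into a Trajectory over the selection atoms."""
        sub = template.subset(self.selection)
        return Trajectory.from_coords(self.frames, sub)


@dataclass
class PathCVValue:
    """One path-CV evaluation: raw s, normalized s_hat, and z (A^2)."""

    s: float
    s_hat: float
    z: float


@dataclass
class PathValidationReport:
    spacing_ok: bool
    topology_ok: bool
    violations: list


def _consecutive_rmsd(frames: np.ndarray) -> np.ndarray:
    out = np.empty(len(frames) - 1)
    for i in range(len(frames) - 1):
        msd, _ = fitted_msd_batch(frames[i], frames[i + 1:i + 2])
        out[i] = np.sqrt(msd[0])
    return out


def _rmsd_to_target(frames: np.ndarray, target: np.ndarray) -> np.ndarray:
    msd, _ = fitted_msd_batch(target, frames)
    return np.sqrt(msd)


def select_frames(
    traj: Trajectory,
    target: Structure,
    bounds: tuple[float, float],
    selection: AtomSelection,
) -> ReferencePath:
    """Greedy forward selection of path frames from a transition trajectory.

    The first frame is kept; each subsequent kept frame is the first whose
    fitted RMSD from the last kept frame enters ``[lo, hi]`` *and* that is
    strictly closer to the target than every previously kept frame
    (topological consecutiveness).  The scan ends at the trajectory frame
    closest to the target, which terminates the path whenever the spacing
    band allows: it is appended if it sits within [lo, hi] of the last kept
    frame, or replaces the last kept frame if that keeps the band.

    Raises
    ------
    PathGapError
        When the spacing from the last kept frame exceeds ``hi`` before any
        candidate qualified (the trajectory has a hole wider than the band).
    """
    lo, hi = bounds
    if not (hi > lo > 0):
        raise ParameterError(f"bounds must satisfy hi > lo > 0, got {bounds}")
    idx = selection.validate(traj.n_atoms)
    target.coords[idx]  # bounds-check target too
    coords = traj.coords[:, idx, :]
    tgt = target.coords[idx]
    d2t = _rmsd_to_target(coords, tgt)
    i_star = int(np.argmin(d2t))

    kept = [0]
    best = d2t[0]
    qualified_since_last = True
    for i in range(1, i_star + 1):
        msd, _ = fitted_msd_batch(coords[kept[-1]], coords[i:i + 1])
        d = float(np.sqrt(msd[0]))
        if lo <= d <= hi and d2t[i] < best:
            kept.append(i)
            best = d2t[i]
            qualified_since_last = True
        elif d > hi:
            if not qualified_since_last:
                raise PathGapError(
                    f"no frame within spacing band ({lo}, {hi}) A between kept frame "
                    f"{kept[-1]} and frame {i}"
                )
            qualified_since_last = False
        if kept[-1] == i:
            qualified_since_last = True

    if kept[-1] != i_star:
        msd, _ = fitted_msd_batch(coords[kept[-1]], coords[i_star:i_star + 1])
        tail = float(np.sqrt(msd[0]))
        if lo <= tail <= hi:
            kept.append(i_star)
        elif tail < lo and len(kept) >= 2:
            msd2, _ = fitted_msd_batch(coords[kept[-2]], coords[i_star:i_star + 1])
            if lo <= float(np.sqrt(msd2[0])) <= hi:
                kept[-1] = i_star
        elif tail < lo and len(kept) == 1:
            pass  # closest approach indistinguishable from the start at this band
    if len(kept) < 2:
        raise PathGapError(
            "fewer than 2 frames selected; trajectory does not traverse the band"
        )
    frames = coords[kept]
    spacing = _consecutive_rmsd(frames)
    path = ReferencePath(frames, 1.0, spacing, AtomSelection(idx.copy(), selection.label))
    path.lam = compute_lambda(path)
    path.kept_indices = np.array(kept)
    return path


def validate_path(path: ReferencePath, target: Structure,
                  bounds: tuple[float, float] = (0.44, 0.60)) -> PathValidationReport:
    """Diagnostic check of spacing band and topological consecutiveness.

    ``topology_ok`` is true iff the fitted RMSD to the target strictly
    decreases along the path; ``spacing_ok`` iff every consecutive RMSD lies
    within ``bounds``.  Violating frame/interval indices are listed.
    """
    lo, hi = bounds
    idx = path.selection.validate(target.n_atoms)
    tgt = target.coords[idx]
    d2t = _rmsd_to_target(path.frames, tgt)
    violations = []
    topology_ok = True
    running_min = d2t[0]
    for j in range(1, len(d2t)):
        if d2t[j] >= running_min:
            topology_ok = False
            violations.append(("topology", j))
        running_min = min(running_min, d2t[j])
    spacing = _consecutive_rmsd(path.frames)
    spacing_ok = True
    for j, d in enumerate(spacing):
        if not (lo <= d <= hi):
            spacing_ok = False
            violations.append(("spacing", j))
    return PathValidationReport(spacing_ok, topology_ok, violations)


def compute_lambda(path: ReferencePath) -> float:
    """lambda = 2.3 / mean per-atom MSD between consecutive path frames (A^-2)."""
    if path.n_frames < 2:
        raise ParameterError("lambda needs >= 2 frames")
    msd = path.spacing ** 2
    mean_msd = float(np.mean(msd))
    if mean_msd <= 0:
        raise DegeneratePathError("coincident consecutive frames (zero spacing)")
    return 2.3 / mean_msd


def _probe_msds(X: np.ndarray, path: ReferencePath) -> tuple[np.ndarray, np.ndarray]:
    if X.shape != path.frames.shape[1:]:
        raise DimensionError(
            f"probe selection shape {X.shape} != path frame shape {path.frames.shape[1:]}"
        )
    return fitted_msd_batch(X, path.frames)


def evaluate_path_cvs(X: Structure | np.ndarray, path: ReferencePath) -> PathCVValue:
    """Evaluate (s, s_hat, z) for one configuration against a reference path.

    ``X`` may be a full :class:`Structure` (the path selection is applied)
    or a raw (M, 3) array already restricted to the path atoms.  Each
    d_j^2 uses an independent optimal superposition; the softmin sums are
    evaluated through log-sum-exp for numerical stability.
    """
    if isinstance(X, Structure):
        coords = X.coords[path.selection.validate(X.n_atoms)]
    else:
        coords = np.asarray(X, dtype=float)
    d2, _ = _probe_msds(coords, path)
    a = -path.lam * d2
    w = softmax(a)
    n = path.n_frames
    s = float(np.dot(np.arange(1, n + 1), w))
    z = float(-logsumexp(a) / path.lam)
    return PathCVValue(s=s, s_hat=(s - 1.0) / (n - 1.0), z=z)


def path_cv_gradients(coords: np.ndarray, path: ReferencePath, n_atoms_total: int | None = None):
    """(s, s_hat, z) and their cartesian gradients for the path atoms.

    ``coords`` is the full structure's coordinates when ``n_atoms_total`` is
    None and coords has more rows than the path selection needs; gradients
    are returned as full (n, 3) arrays with zeros off the selection.  The
    derivative of each fitted d_j^2 uses the envelope theorem: at the
    optimal superposition the rotation/translation derivatives vanish, so

        grad d_j^2 = (2/M) (x_c - R_j^T f_cj)

    with x_c the centred probe and f_cj the centred frame j.
    """
    coords = np.asarray(coords, dtype=float)
    idx = path.selection.indices
    full = coords.shape[0] != path.frames.shape[1]
    probe = coords[idx] if full else coords
    m = probe.shape[0]
    fc, fc2 = path._centred()
    xc = probe - probe.mean(axis=0)
    H = np.einsum("mi,nmj->nij", xc, fc)
    U, S, Vt = np.linalg.svd(H)
    det = np.sign(np.linalg.det(np.einsum("nij,nkj->nik", Vt.transpose(0, 2, 1), U)))
    cross = S[:, 0] + S[:, 1] + det * S[:, 2]
    d2 = ((xc * xc).sum() + fc2 - 2.0 * cross) / m
    np.clip(d2, 0.0, None, out=d2)
    D = np.zeros((len(fc), 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = det
    R = np.einsum("nij,njk,nlk->nil", Vt.transpose(0, 2, 1), D, U)
    a = -path.lam * d2
    w = softmax(a)
    n = path.n_frames
    s = float(np.dot(np.arange(1, n + 1), w))
    z = float(-logsumexp(a) / path.lam)

    # R_j takes centred probe onto centred frame j; map frames back instead
    back = np.einsum("nji,nmj->nmi", R, fc)
    grad_d2 = (2.0 / m) * (xc[None, :, :] - back)  # (N, M, 3)
    j_idx = np.arange(1, n + 1)
    ds_sel = -path.lam * np.einsum("n,nmi->mi", w * (j_idx - s), grad_d2)
    dz_sel = np.einsum("n,nmi->mi", w, grad_d2)
    if full:
        ds = np.zeros_like(coords)
        dz = np.zeros_like(coords)
        ds[idx] = ds_sel
        dz[idx] = dz_sel
    else:
        ds, dz = ds_sel, dz_sel
    s_hat = (s - 1.0) / (n - 1.0)
    return s, s_hat, z, ds, dz
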