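"""Essential dynamics: covariance modes, GROMOS clustering, EDS driver.

The essential subspace is the span of the top principal components (PCs) of
the atomic-fluctuation covariance matrix of a trajectory.  Essential
dynamics sampling (EDS) ratchets a Langevin trajectory toward a target
structure: a trial step is accepted when the fitted RMSD to the target
decreases; otherwise the displacement is corrected inside the retained PC
subspace so the subspace distance to the target does not grow (radial
projection onto the previous constant-distance hypersphere), motion in the
orthogonal complement is kept, and the outward radial velocity component is
removed.  A final guard keeps the previous coordinates when even the
corrected trial would raise the RMSD, which makes the RMSD-to-target trace
monotonically non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import fitted_msd, fitted_msd_batch
from .core import AtomSelection, Structure, Trajectory
from .dynamics import LangevinParams, baoab_step, thermal_velocities
from .errors import (
    InsufficientDataError,
    ParameterError,
    PropagationError,
    SelectionError,
)

__all__ = [
    "EssentialSubspace",
    "ClusterResult",
    "EDSParams",
    "covariance_modes",
    "cluster_gromos",
    "eds_step",
    "run_eds",
    "subspace_radial_correction",
    "save_subspace",
    "load_subspace",
]


@dataclass
class EssentialSubspace:
    """Mean configuration plus orthonormal covariance eigenvectors.

    ``eigenvectors`` has shape (n_modes, 3M) with rows orthonormal and
    eigenvalues (variances, A^2) sorted descending.  ``selection`` records
    the atoms (indices into the parent structure) the analysis used.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    selection: AtomSelection

    def __post_init__(self):
        k, d = self.eigenvectors.shape
        if self.mean.shape != (d // 3, 3):
            raise ParameterError("mean shape inconsistent with eigenvector dimension")
        if len(self.eigenvalues) != k:
            raise ParameterError("eigenvalue count != eigenvector count")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]

    def project(self, coords: np.ndarray, n_modes: int | None = None) -> np.ndarray:
        """Coefficients of a full-structure coordinate set on the first modes."""
        idx = self.selection.indices
        fluct = coords[idx].ravel() - self.mean.ravel()
        E = self.eigenvectors if n_modes is None else self.eigenvectors[:n_modes]
        return E @ fluct

    def cumulative_variance(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.ones_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


@dataclass
class ClusterResult:
    """GROMOS clustering output: frame assignments and centroid frames."""

    assignments: np.ndarray
    centroids: list
    cutoff: float  # nm

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


@dataclass
class EDSParams:
    """EDS driver settings.

    ``subspace_size`` is the number of retained PCs used for the rejection
    correction; ``selection`` defines the distance-to-target metric (fitted
    RMSD).  Propagator settings follow :class:`LangevinParams` conventions.
    """

    subspace_size: int
    selection: AtomSelection
    step_size: float = 0.02  # ps
    temperature: float = 300.0  # K
    friction: float = 5.0  # 1/ps
    mass: float = 12.0  # amu
    seed: int = 0

    def langevin(self) -> LangevinParams:
        return LangevinParams(
            dt=self.step_size,
            friction=self.friction,
            mass=self.mass,
            temperature=self.temperature,
        )


def _iterative_mean_fit(X: np.ndarray, n_iter: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit all frames to their (iteratively refined) mean.

    Returns ``(aligned_frames, mean)``; frames are rotated/translated onto
    the running mean, the standard procedure before covariance analysis.
    """
    ref = X[0]
    aligned = X
    for _ in range(n_iter):
        refc = ref - ref.mean(axis=0)
        _, R = fitted_msd_batch(refc, aligned)
        # R takes centred ref onto each centred frame; transpose inverts
        centred = aligned - aligned.mean(axis=1, keepdims=True)
        aligned = np.einsum("nmi,nij->nmj", centred, R)
        ref = aligned.mean(axis=0)
    return aligned, ref


def covariance_modes(traj: Trajectory, selection: AtomSelection) -> EssentialSubspace:
    """Principal components of the fitted atomic-fluctuation covariance.

    Frames are least-squares fitted to the mean before the covariance is
    accumulated.  Eigenvalues are returned in descending order; each
    eigenvector's sign is fixed so its first non-negligible component is
    positive (deterministic convention).
    """
    if len(traj) < 2:
        raise InsufficientDataError("covariance analysis needs >= 2 frames")
    idx = selection.validate(traj.n_atoms)
    X = traj.coords[:, idx, :]
    aligned, mean = _iterative_mean_fit(X)
    Y = (aligned - mean).reshape(len(traj), -1)
    C = (Y.T @ Y) / len(traj)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    for v in evecs:
        nz = np.flatnonzero(np.abs(v) > 1e-10)
        if len(nz) and v[nz[0]] < 0:
            v *= -1.0
    return EssentialSubspace(mean=mean, eigenvectors=evecs, eigenvalues=evals,
                             selection=AtomSelection(idx.copy(), selection.label))


def pairwise_fitted_rmsd(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of fitted RMSDs between all frame pairs (A)."""
    n = len(coords)
    M = np.zeros((n, n))
    for i in range(n - 1):
        msd, _ = fitted_msd_batch(coords[i], coords[i + 1:])
        M[i, i + 1:] = np.sqrt(msd)
        M[i + 1:, i] = M[i, i + 1:]
    return M


def cluster_gromos(traj: Trajectory, selection: AtomSelection, cutoff: float) -> ClusterResult:
    """Daura (GROMOS) clustering on pairwise fitted RMSD.

    ``cutoff`` is in nm (the field convention); coordinates are in A
    internally.  Iteratively, the frame with the most neighbours within the
    cutoff becomes a centroid, it and its neighbours are removed, and the
    procedure repeats.  Ties break toward the lowest frame index.
    """
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    idx = selection.validate(traj.n_atoms)
    coords = traj.coords[:, idx, :]
    n = len(coords)
    dist = pairwise_fitted_rmsd(coords)
    adj = dist <= cutoff * 10.0
    np.fill_diagonal(adj, True)
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    cluster = 0
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))
        members = np.flatnonzero(adj[center] & remaining)
        assignments[members] = cluster
        centroids.append(center)
        remaining[members] = False
        cluster += 1
    return ClusterResult(assignments=assignments, centroids=centroids, cutoff=cutoff)


def _fitted_rmsd_sel(a: np.ndarray, b: np.ndarray, idx: np.ndarray) -> float:
    msd, _ = fitted_msd(a[idx], b[idx])
    return float(np.sqrt(msd))


def subspace_radial_correction(
    trial: np.ndarray,
    current: np.ndarray,
    target: np.ndarray,
    subspace: EssentialSubspace,
    n_modes: int,
) -> np.ndarray:
    """Project a rejected trial back to the previous subspace distance.

    In the coordinates of the first ``n_modes`` PCs, the trial's position is
    pulled radially toward the target onto the hypersphere of the current
    configuration's distance; the orthogonal-complement displacement is left
    untouched.  Returns the corrected full coordinate array.
    """
    E = subspace.eigenvectors[:n_modes]
    idx = subspace.selection.indices
    c_cur = subspace.project(current, n_modes)
    c_tri = subspace.project(trial, n_modes)
    c_tgt = subspace.project(target, n_modes)
    r_cur = np.linalg.norm(c_cur - c_tgt)
    r_tri = np.linalg.norm(c_tri - c_tgt)
    if r_tri <= r_cur or r_tri == 0.0:
        return trial.copy()
    c_corr = c_tgt + (c_tri - c_tgt) * (r_cur / r_tri)
    corrected = trial.copy()
    corrected[idx] += ((c_corr - c_tri) @ E).reshape(-1, 3)
    return corrected


def eds_step(
    current: Structure,
    velocity: np.ndarray,
    subspace: EssentialSubspace,
    target: Structure,
    force_provider,
    params: EDSParams,
    rng: np.random.Generator,
    force=None,
):
    """One EDS accept/project step.

    Returns ``(next_structure, velocity, accepted, force)``.  ``force`` may
    carry the force at ``current`` between calls to avoid recomputation.
    """
    if params.subspace_size < 1 or params.subspace_size > subspace.n_modes:
        raise ParameterError(
            f"subspace_size must be in [1, {subspace.n_modes}]"
        )
    lp = params.langevin()
    x = current.coords
    if force is None:
        _, force = force_provider(x)
        if not np.all(np.isfinite(force)):
            raise PropagationError("force provider returned non-finite forces")
    sel = params.selection.validate(current.n_atoms)
    rmsd_cur = _fitted_rmsd_sel(x, target.coords, sel)
    x_tri, v_tri, f_tri, _ = baoab_step(x, velocity, force, force_provider, lp, rng)
    rmsd_tri = _fitted_rmsd_sel(x_tri, target.coords, sel)
    if rmsd_tri <= rmsd_cur + 1e-12:
        return current.with_coords(x_tri), v_tri, True, f_tri

    k = params.subspace_size
    x_corr = subspace_radial_correction(x_tri, x, target.coords, subspace, k)
    # remove the outward radial velocity component (in subspace coordinates)
    E = subspace.eigenvectors[:k]
    idx = subspace.selection.indices
    c_tri = subspace.project(x_tri, k)
    c_tgt = subspace.project(target.coords, k)
    r = np.linalg.norm(c_tri - c_tgt)
    v_corr = v_tri.copy()
    if r > 0:
        u = (c_tri - c_tgt) / r
        v_sub = E @ v_tri[idx].ravel()
        outward = float(v_sub @ u)
        if outward > 0:
            v_corr[idx] -= ((outward * u) @ E).reshape(-1, 3)
    rmsd_corr = _fitted_rmsd_sel(x_corr, target.coords, sel)
    if rmsd_corr <= rmsd_cur + 1e-9:
        _, f_corr = force_provider(x_corr)
        return current.with_coords(x_corr), v_corr, False, f_corr
    # even the corrected trial moves away: hold position, keep damped velocity
    return current.with_coords(x.copy()), v_corr, False, force


def run_eds(
    initial: Structure,
    target: Structure,
    subspace: EssentialSubspace,
    n_steps: int,
    force_provider,
    params: EDSParams,
) -> Trajectory:
    """Run EDS from ``initial`` toward ``target``.

    Returns the trajectory of accepted/corrected states (n_steps + 1 frames,
    the initial state first).  The fitted RMSD-to-target sequence over
    ``params.selection`` is attached as ``trajectory.rmsd_to_target`` and is
    monotonically non-increasing; ``trajectory.accepted_fraction`` reports
    the acceptance rate.  Fixed seed gives an identical trajectory.
    """
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    rng = np.random.default_rng(params.seed)
    sel = params.selection.validate(initial.n_atoms)
    lp = params.langevin()
    state = initial.copy()
    velocity = thermal_velocities(state.coords.shape, lp, rng)
    _, force = force_provider(state.coords)
    frames = [state.coords.copy()]
    rmsds = [_fitted_rmsd_sel(state.coords, target.coords, sel)]
    n_accept = 0
    for _ in range(n_steps):
        state, velocity, accepted, force = eds_step(
            state, velocity, subspace, target, force_provider, params, rng, force=force
        )
        n_accept += accepted
        frames.append(state.coords.copy())
        rmsds.append(_fitted_rmsd_sel(state.coords, target.coords, sel))
    traj = Trajectory.from_coords(
        np.array(frames), initial, times=np.arange(n_steps + 1) * params.step_size
    )
    traj.rmsd_to_target = np.array(rmsds)
    traj.accepted_fraction = n_accept / n_steps if n_steps else 0.0
    return traj


def save_subspace(path: str, subspace: EssentialSubspace) -> None:
    """Plain-text eigenvector file: header, selection, mean, eigen pairs."""
    k, d = subspace.eigenvectors.shape
    with open(path, "w") as fh:
        fh.write("# pathmetad essential subspace\n")
        fh.write(f"# n_atoms {d // 3} n_modes {k} label {subspace.selection.label}\n")
        fh.write("# selection " + " ".join(map(str, subspace.selection.indices)) + "\n")
        fh.write("# mean (x y z per atom)\n")
        for row in subspace.mean:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
        fh.write("# eigenvalue then 3M components, one mode per line\n")
        for lam, vec in zip(subspace.eigenvalues, subspace.eigenvectors):
            fh.write(f"{lam:.10g} " + " ".join(f"{v:.10g}" for v in vec) + "\n")


def load_subspace(path: str) -> EssentialSubspace:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    meta = lines[1].split()
    n_atoms, n_modes = int(meta[2]), int(meta[4])
    label = meta[6] if len(meta) > 6 else "selection"
    sel = AtomSelection(np.array([int(v) for v in lines[2].split()[2:]]), label)
    mean = np.array([[float(v) for v in lines[4 + i].split()] for i in range(n_atoms)])
    start = 5 + n_atoms
    evals, evecs = [], []
    for line in lines[start:start + n_modes]:
        parts = [float(v) for v in line.split()]
        evals.append(parts[0])
        evecs.append(parts[1:])
    return EssentialSubspace(
        mean=mean,
        eigenvectors=np.array(evecs),
        eigenvalues=np.array(evals),
        selection=sel,
    )
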