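"""Free-energy surfaces, minimum free energy paths and error estimates.

The converged well-tempered bias relates to the free energy as
F = -(gamma/(gamma-1)) * V_hills (within a constant); surfaces are reported
in kcal/mol with the global minimum shifted to zero.  The MFEP is the
per-bin minimum over z of F(s_hat, z) on 25 equal-width s_hat bins, and its
stepwise decomposition reports, for every ascending segment, the barrier
(following maximum minus preceding minimum) and the net free-energy change
(next minimum minus preceding minimum); the rate-determining step is the
largest barrier.

Statistical errors use constant-final-bias reweighting (weights
proportional to exp(+V_final/kT)) followed by block averaging: samples are
discretized into the 25 s_hat bins and, for a range of block sizes, the
free-energy error of each bin is propagated from the standard error of its
per-block weighted population, err_F = kT * SEM(p) / mean(p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KB, KJ_PER_KCAL
from .errors import (
    EmptyBiasError,
    GridResolutionError,
    InsufficientDataError,
    ParameterError,
)
from .metad import BiasPotential

__all__ = [
    "FreeEnergySurface",
    "MFEPProfile",
    "fes_from_bias",
    "extract_mfep",
    "profile_barriers",
    "reweight_series",
    "blocked_sem",
    "block_error_scan",
    "write_fes_tsv",
    "write_mfep_tsv",
]


@dataclass
class FreeEnergySurface:
    """Gridded F in kcal/mol, min-shifted to 0.

    2-D surfaces have ``F[i, j]`` at (s_hat_grid[i], z_grid[j]); 1-D
    profiles have ``z_grid is None`` and ``F`` matching ``s_hat_grid``.
    """

    s_hat_grid: np.ndarray
    z_grid: np.ndarray | None
    F: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.F)):
            raise ParameterError("free energy grid must be finite")


@dataclass
class MFEPProfile:
    """Per-bin minimum free energy path: (s_hat centre, argmin z, F)."""

    bin_centers: np.ndarray
    z_at_min: np.ndarray | None
    F: np.ndarray  # kcal/mol, referenced to the first bin

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def fes_from_bias(
    bias: BiasPotential,
    s_grid: np.ndarray,
    z_grid: np.ndarray | None = None,
    n_path_frames: int | None = None,
) -> FreeEnergySurface:
    """Free energy from the final bias: F = -(gamma/(gamma-1)) V_hills.

    The wall is excluded.  ``s_grid`` is interpreted as the axis the bias
    was deposited on, unless ``n_path_frames`` is given, in which case
    ``s_grid`` is a normalized s_hat axis and hill centres (raw s units) are
    probed at s = 1 + s_hat (N - 1).  Result in kcal/mol, min-shifted to 0.
    """
    if bias.n_hills == 0:
        raise EmptyBiasError("cannot estimate a free energy from an empty bias")
    gamma = bias.params.gamma
    prefac = -gamma / (gamma - 1.0)
    s_eval = np.asarray(s_grid, dtype=float)
    if n_path_frames is not None:
        s_eval = 1.0 + s_eval * (n_path_frames - 1.0)
    if z_grid is None:
        if bias.ndim != 1:
            raise ParameterError("bias is 2-D; a z grid is required")
        V = np.array([bias.hills_energy([s]) for s in s_eval])
        F = prefac * V / KJ_PER_KCAL
        return FreeEnergySurface(np.asarray(s_grid, float), None, F - F.min())
    z_eval = np.asarray(z_grid, dtype=float)
    V = np.empty((len(s_eval), len(z_eval)))
    for i, s in enumerate(s_eval):
        for j, z in enumerate(z_eval):
            V[i, j] = bias.hills_energy([s, z])
    F = prefac * V / KJ_PER_KCAL
    return FreeEnergySurface(np.asarray(s_grid, float), z_eval, F - F.min())


def extract_mfep(fes: FreeEnergySurface, n_bins: int = 25) -> MFEPProfile:
    """Per-s_hat-bin minimum of F over z (and over s_hat within the bin).

    The s_hat axis [0, 1] is divided into ``n_bins`` equal bins; within each
    bin the grid node with the lowest F is taken, recording its z.  The
    profile is referenced to the first bin's value.

    Raises
    ------
    GridResolutionError
        If a bin contains no grid nodes.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    zmins = np.empty(n_bins)
    fmins = np.empty(n_bins)
    s = fes.s_hat_grid
    for b in range(n_bins):
        hi_cmp = s <= edges[b + 1] if b == n_bins - 1 else s < edges[b + 1]
        mask = (s >= edges[b]) & hi_cmp
        if not mask.any():
            raise GridResolutionError(
                f"s_hat bin {b} ({edges[b]:.3f}-{edges[b + 1]:.3f}) contains no grid nodes"
            )
        if fes.z_grid is None:
            sub = fes.F[mask]
            k = int(np.argmin(sub))
            fmins[b] = sub[k]
            zmins[b] = np.nan
        else:
            sub = fes.F[mask, :]
            i, j = np.unravel_index(np.argmin(sub), sub.shape)
            fmins[b] = sub[i, j]
            zmins[b] = fes.z_grid[j]
    return MFEPProfile(
        bin_centers=centers,
        z_at_min=None if fes.z_grid is None else zmins,
        F=fmins - fmins[0],
    )


def _local_extrema(F: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local minima and maxima of a 1-D profile (plateau-tolerant)."""
    n = len(F)
    minima, maxima = [], []
    for i in range(n):
        left = F[i - 1] if i > 0 else np.inf
        right = F[i + 1] if i < n - 1 else np.inf
        if F[i] <= left and F[i] <= right and (F[i] < left or F[i] < right or n == 1):
            minima.append(i)
        left = F[i - 1] if i > 0 else -np.inf
        right = F[i + 1] if i < n - 1 else -np.inf
        if F[i] >= left and F[i] >= right and (F[i] > left or F[i] > right):
            maxima.append(i)
    # collapse adjacent plateau duplicates
    minima = [m for k, m in enumerate(minima) if k == 0 or m > minima[k - 1] + 1 or F[m] != F[minima[k - 1]]]
    return minima, maxima


def profile_barriers(profile: MFEPProfile) -> list[tuple[float, float]]:
    """Step decomposition of an MFEP profile.

    Each ascending segment contributes ``(barrier, net_dF)`` where the
    barrier is the following maximum minus the preceding minimum and the net
    change is the next minimum minus the preceding minimum.  A monotone
    decreasing profile has no steps.  The rate-determining barrier is
    ``max(step[0] for step in steps)`` (0 if empty).
    """
    F = np.asarray(profile.F, dtype=float)
    if len(F) == 0:
        raise ParameterError("empty profile")
    minima, maxima = _local_extrema(F)
    steps: list[tuple[float, float]] = []
    for k, m in enumerate(minima):
        following = [M for M in maxima if M > m]
        if not following:
            continue
        M = following[0]
        later_minima = [mm for mm in minima if mm > M]
        nxt = later_minima[0] if later_minima else int(np.argmin(F[M:]) + M)
        steps.append((float(F[M] - F[m]), float(F[nxt] - F[m])))
    return steps


def rate_determining_barrier(steps: list[tuple[float, float]]) -> float:
    return max((b for b, _ in steps), default=0.0)


def reweight_series(cv_log, final_bias: BiasPotential, temperature: float = 300.0) -> np.ndarray:
    """Constant-final-bias unbiasing weights, normalized to sum 1.

    ``w_i propto exp(+V_final(s_i, z_i) / kT)``: the bias is assumed
    constant throughout the run and equal to its final state, the standard
    reweighting for well-tempered runs.  ``cv_log`` is the DataFrame from
    :func:`pathmetad.metad.run_wt_metad` (columns s [, z]).
    """
    if len(cv_log) == 0:
        raise InsufficientDataError("cv log is empty")
    kt = KB * temperature
    if final_bias.ndim == 2:
        pts = cv_log[["s", "z"]].to_numpy(dtype=float)
    else:
        pts = cv_log[["s"]].to_numpy(dtype=float)
    V = np.array([final_bias.hills_energy(p) for p in pts])
    a = V / kt
    a -= a.max()  # overflow guard
    w = np.exp(a)
    return w / w.sum()


def blocked_sem(x: np.ndarray, block_size: int, weights: np.ndarray | None = None) -> float:
    """Standard error of the mean from contiguous block means.

    Trailing samples that do not fill a block are dropped.  With weights,
    block means are weighted within each block.
    """
    x = np.asarray(x, dtype=float)
    if block_size < 1 or block_size > len(x):
        raise ParameterError("block size must be in [1, len(series)]")
    n_blocks = len(x) // block_size
    xb = x[: n_blocks * block_size].reshape(n_blocks, block_size)
    if weights is None:
        means = xb.mean(axis=1)
    else:
        w = np.asarray(weights, dtype=float)[: n_blocks * block_size].reshape(n_blocks, block_size)
        means = (xb * w).sum(axis=1) / w.sum(axis=1)
    if n_blocks < 2:
        raise ParameterError("need >= 2 blocks for a standard error")
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def block_error_scan(
    s_hat: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = 25,
    block_sizes=range(10, 501, 10),
    temperature: float = 300.0,
) -> np.ndarray:
    """Mean per-bin free-energy error vs block size.

    ``s_hat`` samples are discretized into ``n_bins`` equal bins on [0, 1];
    for each block size B the per-block weighted population fraction of each
    bin is formed and the bin's free-energy error is
    ``kT * SEM(p) / mean(p)`` (kcal/mol).  The mean over occupied bins is
    reported; returns an array of rows (B, mean_error).
    """
    s_hat = np.asarray(s_hat, dtype=float)
    block_sizes = list(block_sizes)
    if max(block_sizes) > len(s_hat):
        raise ParameterError(
            f"largest block size {max(block_sizes)} exceeds sample count {len(s_hat)}"
        )
    w = np.ones_like(s_hat) if weights is None else np.asarray(weights, dtype=float)
    kt_kcal = KB * temperature / KJ_PER_KCAL
    bins = np.clip((s_hat * n_bins).astype(int), 0, n_bins - 1)
    rows = []
    for B in block_sizes:
        n_blocks = len(s_hat) // B
        m = n_blocks * B
        bin_blk = bins[:m].reshape(n_blocks, B)
        w_blk = w[:m].reshape(n_blocks, B)
        wsum = w_blk.sum(axis=1)
        errors = []
        for k in range(n_bins):
            pop = np.where(bin_blk == k, w_blk, 0.0).sum(axis=1) / wsum
            mean = pop.mean()
            if mean <= 0:
                continue  # unoccupied bin: missing, not zero
            sem = pop.std(ddof=1) / np.sqrt(n_blocks)
            errors.append(kt_kcal * sem / mean)
        rows.append((B, float(np.mean(errors)) if errors else np.nan))
    return np.array(rows)


def write_fes_tsv(path: str, fes: FreeEnergySurface) -> None:
    """3-column TSV (s_hat, z, F) for 2-D surfaces; (s_hat, F) for profiles."""
    with open(path, "w") as fh:
        if fes.z_grid is None:
            fh.write("#! FIELDS s_hat free_energy\n")
            for s, f in zip(fes.s_hat_grid, fes.F):
                fh.write(f"{s:.8g}\t{f:.8g}\n")
        else:
            fh.write("#! FIELDS s_hat z free_energy\n")
            for i, s in enumerate(fes.s_hat_grid):
                for j, z in enumerate(fes.z_grid):
                    fh.write(f"{s:.8g}\t{z:.8g}\t{fes.F[i, j]:.8g}\n")


def write_mfep_tsv(path: str, profile: MFEPProfile) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS bin_center z_min free_energy\n")
        z = profile.z_at_min
        for b in range(profile.n_bins):
            zv = float("nan") if z is None else z[b]
            fh.write(f"{profile.bin_centers[b]:.8g}\t{zv:.8g}\t{profile.F[b]:.8g}\n")
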