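"""Low-level superposition kernels shared by the public API and hot loops.

Conventions: a mobile point set P is rotated onto a reference Q; both are
centred first.  ``kabsch_rotation`` returns R with det(R) = +1 such that
R @ p_i approximates q_i in the least-squares sense.  The batched variant
aligns one probe configuration against a stack of reference frames in a
single vectorised SVD call, which is the inner loop of path-CV evaluation.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateFitError, DimensionError


def centroid(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=0)


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centred ``P`` onto centred ``Q``.

    Parameters are (n, 3) arrays already centred at the origin.  The
    reflection case (det < 0) is corrected by flipping the smallest
    singular direction, so the result is always a proper rotation.
    """
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def fitted_msd(P: np.ndarray, Q: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-atom mean squared displacement of P vs Q after optimal superposition.

    Returns ``(msd, R)`` where R is the rotation applied to centred P.
    """
    if P.shape != Q.shape:
        raise DimensionError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # msd via the singular-value identity avoids forming the rotated set
    cross = S[0] + S[1] + d * S[2]
    msd = ((Pc * Pc).sum() + (Qc * Qc).sum() - 2.0 * cross) / n
    msd = max(msd, 0.0)
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return float(msd), R


def fitted_msd_batch(x: np.ndarray, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MSD of one probe ``x`` (M, 3) against a stack of frames (N, M, 3).

    All superpositions are done in a single batched SVD.  Returns
    ``(msd (N,), R (N, 3, 3))`` with R_j the rotation taking centred x onto
    centred frame j.
    """
    if x.ndim != 2 or frames.ndim != 3 or frames.shape[1:] != x.shape:
        raise DimensionError(
            f"probe shape {x.shape} incompatible with frame stack {frames.shape}"
        )
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    fc = frames - frames.mean(axis=1, keepdims=True)
    H = np.einsum("mi,nmj->nij", xc, fc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("nij,nkj->nik", Vt.transpose(0, 2, 1), U)))
    # det(V U^T); sign corrects improper rotations per frame
    cross = S[:, 0] + S[:, 1] + d * S[:, 2]
    msd = ((xc * xc).sum() + (fc * fc).sum(axis=(1, 2)) - 2.0 * cross) / n
    np.clip(msd, 0.0, None, out=msd)
    D = np.zeros((len(frames), 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("nij,njk,nlk->nil", Vt.transpose(0, 2, 1), D, U)
    return msd, R


def check_fit_points(P: np.ndarray) -> None:
    """Raise DegenerateFitError for < 3 points or a collinear set."""
    if P.shape[0] < 3:
        raise DegenerateFitError(f"superposition needs >= 3 fit atoms, got {P.shape[0]}")
    Pc = P - P.mean(axis=0)
    s = np.linalg.svd(Pc, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateFitError("fit atoms are collinear (rank-deficient point set)")
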