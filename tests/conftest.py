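"""Shared fixtures: toy systems, reference paths, and the one heavy pipeline run."""

import numpy as np
import pytest
from scipy.optimize import brentq

import pathmetad as pm
from pathmetad._linalg import fitted_msd
from pathmetad.core import AtomSelection, Structure, Trajectory


@pytest.fixture(scope="session")
def two_state():
    return pm.make_two_state_system(n_beads=30, target_rmsd=5.0, barrier=6.0, seed=0)


@pytest.fixture(scope="session")
def small_structure():
    rng = np.random.default_rng(7)
    return Structure(rng.normal(size=(8, 3)) * 3.0)


def uniformly_spaced_line_trajectory(n_frames: int, spacing: float, n_atoms: int = 12,
                                     seed: int = 5):
    """Trajectory moving along a fixed mean-zero displacement field.

    The per-step amplitude is root-solved so the fitted RMSD between
    consecutive frames equals ``spacing`` (within solver precision); frames
    advance along a straight line in configuration space toward the last
    frame, so the distance to the final frame decreases monotonically.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3)) * 4.0
    u = rng.normal(size=(n_atoms, 3))
    u -= u.mean(axis=0)
    # remove infinitesimal-rotation components (sum_i x_ci x u_i = 0) so the
    # optimal superposition between any two frames is the identity and the
    # fitted RMSD equals the plain displacement norm, exactly
    centred = base - base.mean(axis=0)
    gens = [np.cross(np.tile(ax, (n_atoms, 1)), centred).ravel() for ax in np.eye(3)]
    G = np.array(gens)
    coef = np.linalg.solve(G @ G.T, G @ u.ravel())
    u = (u.ravel() - coef @ G).reshape(n_atoms, 3)
    u -= u.mean(axis=0)
    u /= np.sqrt((u * u).sum() / n_atoms)

    def spacing_at(c):
        msd, _ = fitted_msd(base, base + c * u)
        return np.sqrt(msd) - spacing

    c = brentq(spacing_at, 1e-9, 10 * spacing, xtol=1e-15)
    coords = np.array([base + j * c * u for j in range(n_frames)])
    return Trajectory.from_coords(coords, Structure(base))


@pytest.fixture(scope="session")
def line_trajectory():
    return uniformly_spaced_line_trajectory(n_frames=11, spacing=0.5)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full default-config pipeline run (EDS -> path -> wT-metaD -> MFEP)."""
    return pm.run_pipeline(seed=11)
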