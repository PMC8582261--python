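"""Langevin (BAOAB) propagation on toy force providers.

Units: coordinates A, time ps, mass amu, energy kJ/mol.  The conversion
1 kJ/mol / (amu * A) = 100 A/ps^2 enters as ``ACCEL``.  A force provider is
any callable ``f(coords) -> (energy, forces)`` with forces in kJ/mol/A and
the same shape as ``coords``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KB
from .errors import PropagationError

#: (kJ/mol/A)/amu expressed in A/ps^2
ACCEL = 100.0


@dataclass
class LangevinParams:
    """Propagator settings: dt (ps), friction (1/ps), mass (amu), T (K)."""

    dt: float = 0.005
    friction: float = 5.0
    mass: float = 12.0
    temperature: float = 300.0

    @property
    def kt(self) -> float:
        return KB * self.temperature


def thermal_velocities(shape, params: LangevinParams, rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(params.kt * ACCEL / params.mass)
    return sigma * rng.standard_normal(shape)


def baoab_step(x, v, force, force_fn, params: LangevinParams, rng: np.random.Generator):
    """One BAOAB Langevin step.

    ``force`` is the force at ``x`` (avoids recomputation); returns
    ``(x_new, v_new, force_new, energy_new)``.
    """
    dt, m = params.dt, params.mass
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(params.kt * ACCEL / m) * np.sqrt(1.0 - c1 * c1)
    v = v + 0.5 * dt * (ACCEL / m) * force
    x = x + 0.5 * dt * v
    v = c1 * v + c2 * rng.standard_normal(np.shape(x))
    x = x + 0.5 * dt * v
    energy, f_new = force_fn(x)
    if not np.all(np.isfinite(f_new)):
        raise PropagationError("force provider returned non-finite forces")
    v = v + 0.5 * dt * (ACCEL / m) * f_new
    return x, v, f_new, energy


def sample_basin(x0: np.ndarray, force_fn, n_steps: int, save_every: int,
                 params: LangevinParams, rng: np.random.Generator) -> np.ndarray:
    """Unbiased Langevin run; returns saved coordinate snapshots (n, *shape)."""
    x = np.array(x0, dtype=float)
    v = thermal_velocities(x.shape, params, rng)
    _, f = force_fn(x)
    out = []
    for step in range(1, n_steps + 1):
        x, v, f, _ = baoab_step(x, v, f, force_fn, params, rng)
        if step % save_every == 0:
            out.append(x.copy())
    return np.array(out)
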