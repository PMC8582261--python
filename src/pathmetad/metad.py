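"""Well-tempered metadynamics over path CVs or analytic CV-space potentials.

A history-dependent bias V(s, z) is built from Gaussian hills deposited
every ``stride`` steps.  In the well-tempered scheme the height of each new
hill is damped by the bias already present at the deposition point,

    h = w0 * exp(-V_hills(s, z) / (kB * dT)),   dT = (gamma - 1) * T,

so the bias converges to -(gamma-1)/gamma times the free energy (within a
constant).  Exploration of high-z regions is limited by a one-sided
harmonic wall 0.5 * wall_k * (z - z_max)^2 for z > z_max.

Two system kinds are supported by :func:`run_wt_metad`: an analytic
CV-space potential (1D or 2D; the CVs are the coordinates themselves) and a
toy molecular system biased through the path CVs of
:mod:`pathmetad.pathcv` (chain rule through the CV gradients).  Hills on a
molecular system are deposited in *raw* s (frame-index) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import KB, Structure
from .dynamics import ACCEL, LangevinParams, baoab_step, thermal_velocities
from .errors import EmptyBiasError, NumericError, ParameterError, PropagationError
from .pathcv import ReferencePath, path_cv_gradients

__all__ = [
    "MetaDParams",
    "BiasPotential",
    "PathCVSystem",
    "deposit_gaussian",
    "bias_value",
    "run_wt_metad",
    "write_hills",
    "read_hills",
    "write_colvar",
    "read_colvar",
]

#: hills are truncated beyond this many widths from their centre
HILL_CUTOFF_SIGMA = 6.0


@dataclass
class MetaDParams:
    """Well-tempered metadynamics settings.

    Defaults follow the kinase-activation protocol: hills every 500 steps,
    initial height 0.5 kJ/mol, bias factor 30, widths 2.0 (raw s units) and
    0.005 A^2 (z), one-sided z wall at 3.0 A^2 with force constant
    1e4 kJ mol^-1 A^-4 on (z - z_max)^2.
    """

    temperature: float = 300.0  # K
    gamma: float = 30.0  # bias factor
    w0: float = 0.5  # kJ/mol
    stride: int = 500  # steps between deposits
    sigma_s: float = 2.0  # raw s units
    sigma_z: float = 0.005  # A^2
    z_max: float = 3.0  # A^2
    wall_k: float = 1.0e4  # kJ mol^-1 A^-4
    use_wall: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 1:
            raise ParameterError("bias factor gamma must be > 1")
        if self.w0 <= 0:
            raise ParameterError("initial hill height must be > 0")
        if self.sigma_s <= 0 or self.sigma_z <= 0:
            raise ParameterError("Gaussian widths must be > 0")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")

    @property
    def kt(self) -> float:
        return KB * self.temperature

    @property
    def delta_t_energy(self) -> float:
        """kB * (gamma - 1) * T, the well-tempered damping energy (kJ/mol)."""
        return KB * (self.gamma - 1.0) * self.temperature


class BiasPotential:
    """Ordered list of deposited Gaussian hills plus the wall parameters.

    ``ndim`` is 1 for a single CV or 2 for (s, z); the wall acts on the last
    coordinate (z) of a 2-D bias only.
    """

    def __init__(self, params: MetaDParams, ndim: int = 2):
        if ndim not in (1, 2):
            raise ParameterError("bias dimension must be 1 or 2")
        self.params = params
        self.ndim = ndim
        self.centers: list[np.ndarray] = []
        self.sigmas: list[np.ndarray] = []
        self.heights: list[float] = []
        self.times: list[float] = []
        self._c = np.empty((0, ndim))
        self._s = np.empty((0, ndim))
        self._h = np.empty(0)

    @property
    def n_hills(self) -> int:
        return len(self.heights)

    def _default_sigma(self) -> np.ndarray:
        if self.ndim == 1:
            return np.array([self.params.sigma_s])
        return np.array([self.params.sigma_s, self.params.sigma_z])

    def add_hill(self, center, height: float, time: float, sigma=None) -> None:
        center = np.atleast_1d(np.asarray(center, dtype=float))
        if center.shape != (self.ndim,):
            raise ParameterError(f"hill centre must have {self.ndim} components")
        if self.times and time <= self.times[-1]:
            raise ParameterError("hill times must be strictly increasing")
        sigma = self._default_sigma() if sigma is None else np.atleast_1d(sigma)
        self.centers.append(center)
        self.sigmas.append(sigma)
        self.heights.append(float(height))
        self.times.append(float(time))
        self._c = np.vstack([self._c, center[None, :]])
        self._s = np.vstack([self._s, sigma[None, :]])
        self._h = np.append(self._h, float(height))

    def hills_energy(self, at) -> float:
        """Gaussian-hill bias only (no wall), kJ/mol."""
        e, _ = self._hills_energy_grad(np.atleast_1d(np.asarray(at, dtype=float)))
        return e

    def _hills_energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        if self.n_hills == 0:
            return 0.0, np.zeros(self.ndim)
        u = (x[None, :] - self._c) / self._s
        mask = np.all(np.abs(u) <= HILL_CUTOFF_SIGMA, axis=1)
        if not mask.any():
            return 0.0, np.zeros(self.ndim)
        u = u[mask]
        g = self._h[mask] * np.exp(-0.5 * (u * u).sum(axis=1))
        energy = float(g.sum())
        grad = -(g[:, None] * u / self._s[mask]).sum(axis=0)
        return energy, grad

    def _wall_energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros(self.ndim)
        if self.ndim != 2 or not self.params.use_wall:
            return 0.0, grad
        z = x[1]
        if z <= self.params.z_max:
            return 0.0, grad
        dz = z - self.params.z_max
        grad[1] = self.params.wall_k * dz
        return 0.5 * self.params.wall_k * dz * dz, grad

    def value_and_grad(self, at) -> tuple[float, np.ndarray]:
        """Total bias (hills + wall) and its analytic gradient at a point."""
        x = np.atleast_1d(np.asarray(at, dtype=float))
        if not np.all(np.isfinite(x)):
            raise NumericError("bias evaluation point must be finite")
        eh, gh = self._hills_energy_grad(x)
        ew, gw = self._wall_energy_grad(x)
        return eh + ew, gh + gw


def deposit_gaussian(bias: BiasPotential, at, params: MetaDParams, time: float | None = None) -> BiasPotential:
    """Deposit one well-tempered hill at ``at``; returns the (mutated) bias.

    The height is ``w0 * exp(-V_hills(at) / kB dT)`` with the hill bias
    evaluated *before* the deposit (the wall never damps hills).
    """
    x = np.atleast_1d(np.asarray(at, dtype=float))
    if not np.all(np.isfinite(x)):
        raise NumericError("deposition point must be finite")
    v = bias.hills_energy(x)
    if not np.isfinite(v):
        raise NumericError("bias is non-finite at the deposition point")
    height = params.w0 * np.exp(-v / params.delta_t_energy)
    t = time if time is not None else (bias.times[-1] + 1.0 if bias.times else 0.0)
    bias.add_hill(x, height, t)
    return bias


def bias_value(bias: BiasPotential, at) -> tuple[float, ...]:
    """Energy (kJ/mol) and gradient components of the bias (hills + wall)."""
    e, g = bias.value_and_grad(at)
    return (e, *g)


@dataclass
class PathCVSystem:
    """A toy molecular system biased through path CVs.

    ``force_provider(coords) -> (energy, forces)`` supplies the physical
    forces; ``path`` defines s and z.  ``initial`` seeds the propagation.
    """

    force_provider: object
    path: ReferencePath
    initial: Structure


def _run_cv_space(system, params, n_steps, langevin, log_stride):
    ndim = system.ndim
    bias = BiasPotential(params, ndim=ndim)
    rng = np.random.default_rng(params.seed)
    x = np.array(system.start, dtype=float)
    v = thermal_velocities(x.shape, langevin, rng)

    def total_force(pos):
        e_sys = system.value(pos)
        g_sys = system.grad(pos)
        e_b, g_b = bias.value_and_grad(pos)
        return e_sys + e_b, -(g_sys + g_b)

    _, f = total_force(x)
    rows = []
    for step in range(1, n_steps + 1):
        x, v, f, _ = baoab_step(x, v, f, total_force, langevin, rng)
        if not np.all(np.isfinite(x)):
            raise PropagationError(f"non-finite CVs at step {step}")
        if step % params.stride == 0:
            deposit_gaussian(bias, x, params, time=step * langevin.dt)
            _, f = total_force(x)  # bias changed under the walker
        if step % log_stride == 0:
            e_b, _ = bias.value_and_grad(x)
            if ndim == 1:
                rows.append((step * langevin.dt, x[0], e_b))
            else:
                rows.append((step * langevin.dt, x[0], x[1], e_b))
    cols = ["time", "s", "bias"] if ndim == 1 else ["time", "s", "z", "bias"]
    return pd.DataFrame(rows, columns=cols), bias


def _run_molecular(system: PathCVSystem, params, n_steps, langevin, log_stride):
    bias = BiasPotential(params, ndim=2)
    rng = np.random.default_rng(params.seed)
    path = system.path
    x = np.array(system.initial.coords, dtype=float)
    v = thermal_velocities(x.shape, langevin, rng)
    state = {"cv": None}

    def total_force(pos):
        e_sys, f_sys = system.force_provider(pos)
        s, s_hat, z, ds, dz = path_cv_gradients(pos, path)
        e_b, g_b = bias.value_and_grad(np.array([s, z]))
        state["cv"] = (s, s_hat, z, e_b)
        return e_sys + e_b, f_sys - g_b[0] * ds - g_b[1] * dz

    _, f = total_force(x)
    rows = []
    for step in range(1, n_steps + 1):
        x, v, f, _ = baoab_step(x, v, f, total_force, langevin, rng)
        s, s_hat, z, e_b = state["cv"]
        if not (np.isfinite(s) and np.isfinite(z)):
            raise PropagationError(f"non-finite CVs at step {step}")
        if step % params.stride == 0:
            deposit_gaussian(bias, np.array([s, z]), params, time=step * langevin.dt)
            _, f = total_force(x)
        if step % log_stride == 0:
            rows.append((step * langevin.dt, s, s_hat, z, e_b))
    return pd.DataFrame(rows, columns=["time", "s", "s_hat", "z", "bias"]), bias


def run_wt_metad(
    system,
    params: MetaDParams,
    n_steps: int,
    langevin: LangevinParams | None = None,
    log_stride: int = 1,
) -> tuple[pd.DataFrame, BiasPotential]:
    """Run well-tempered metadynamics for ``n_steps``.

    ``system`` is either an analytic CV-space potential (object with
    ``ndim``, ``start``, ``value(x)``, ``grad(x)``; e.g. from
    :func:`pathmetad.fixtures.make_analytic_fes`) or a
    :class:`PathCVSystem`.  Returns ``(cv_log, bias)``; the log is a tidy
    DataFrame with time (ps), the CV values and the bias at each logged
    step.  A fixed ``params.seed`` gives bit-identical output.
    """
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    lp = langevin if langevin is not None else LangevinParams(temperature=params.temperature)
    if n_steps == 0:
        if isinstance(system, PathCVSystem):
            cols = ["time", "s", "s_hat", "z", "bias"]
            return pd.DataFrame(columns=cols), BiasPotential(params, ndim=2)
        cols = ["time", "s", "bias"] if system.ndim == 1 else ["time", "s", "z", "bias"]
        return pd.DataFrame(columns=cols), BiasPotential(params, ndim=system.ndim)
    if isinstance(system, PathCVSystem):
        return _run_molecular(system, params, n_steps, lp, log_stride)
    return _run_cv_space(system, params, n_steps, lp, log_stride)


# --- HILLS / COLVAR style TSV interop -------------------------------------

def write_hills(path: str, bias: BiasPotential) -> None:
    """HILLS-style TSV with a '#!' header, one deposited hill per row."""
    p = bias.params
    with open(path, "w") as fh:
        if bias.ndim == 1:
            fh.write("#! FIELDS time center_s sigma_s height biasf\n")
            for t, c, s, h in zip(bias.times, bias.centers, bias.sigmas, bias.heights):
                fh.write(f"{t:.6f}\t{c[0]:.10g}\t{s[0]:.10g}\t{h:.10g}\t{p.gamma:.6g}\n")
        else:
            fh.write("#! FIELDS time center_s center_z sigma_s sigma_z height biasf\n")
            for t, c, s, h in zip(bias.times, bias.centers, bias.sigmas, bias.heights):
                fh.write(
                    f"{t:.6f}\t{c[0]:.10g}\t{c[1]:.10g}\t{s[0]:.10g}\t{s[1]:.10g}"
                    f"\t{h:.10g}\t{p.gamma:.6g}\n"
                )


def read_hills(path: str, params: MetaDParams | None = None) -> BiasPotential:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#!"):
            raise ParameterError("not a HILLS file: missing '#!' header")
        fields = header.split()[2:]
        ndim = 2 if "center_z" in fields else 1
        rows = [list(map(float, line.split())) for line in fh if line.strip()]
    if params is None:
        gamma = rows[0][-1] if rows else 30.0
        params = MetaDParams(gamma=gamma)
    bias = BiasPotential(params, ndim=ndim)
    for r in rows:
        if ndim == 1:
            t, cs, ss, h = r[0], r[1], r[2], r[3]
            bias.add_hill([cs], h, t, sigma=[ss])
        else:
            t, cs, cz, ss, sz, h = r[0], r[1], r[2], r[3], r[4], r[5]
            bias.add_hill([cs, cz], h, t, sigma=[ss, sz])
    return bias


def write_colvar(path: str, cv_log: pd.DataFrame) -> None:
    """COLVAR-style TSV with a '#!' header line."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cv_log.columns) + "\n")
        cv_log.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_colvar(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#!"):
        raise ParameterError("not a COLVAR file: missing '#!' header")
    cols = header.split()[2:]
    return pd.read_csv(path, sep="\t", comment="#", names=cols)
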