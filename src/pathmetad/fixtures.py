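"""Deterministic synthetic systems: every input class the toolkit needs.

The generators stand in, at desk scale, for the inputs a kinase-activation
study would take from production MD: a two-state bead chain with a
double-basin potential (inactive/active endpoints ~5 A apart), interpolated
trajectories with controlled frame spacing, analytic free-energy landscapes
with known minima/barriers/valleys, and autocorrelated time series with
known statistics.  All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import softmax

from ._linalg import fitted_msd
from .core import KB, Structure, Trajectory
from .errors import ConstructionError, DimensionError, ParameterError
from .fes import MFEPProfile

__all__ = [
    "TwoStateSystem",
    "make_two_state_system",
    "make_interpolated_trajectory",
    "make_analytic_fes",
    "make_ar1_series",
    "DoubleWell1D",
    "CurvedValley2D",
    "ThreeStepProfile",
    "AR1Series",
]


@dataclass
class TwoStateSystem:
    """Toy two-state bead chain with a smooth double-basin potential.

    ``force_provider(coords) -> (energy kJ/mol, forces kJ/mol/A)``; both
    endpoint structures are exact minima.  ``metadata`` records the
    calibrated spring constant, mixing temperature and achieved barrier.
    """

    state_a: Structure
    state_b: Structure
    force_provider: object
    target_rmsd: float
    barrier_kt: float
    metadata: dict = field(default_factory=dict)


def _helix_chain(n: int) -> np.ndarray:
    """C-alpha-like helix: radius 2.3 A, 100 deg twist, 1.5 A rise."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _extended_chain(n: int) -> np.ndarray:
    """Extended conformation: straight line, 3.6 A spacing."""
    i = np.arange(n)
    return np.column_stack([np.zeros(n), np.zeros(n), 3.6 * i])


class _DoubleBasinForce:
    """Exponential mixing of two anisotropic harmonic-network basins.

    V = -(1/beta*) ln[exp(-beta* V_A) + exp(-beta* V_B)] where each basin is
    harmonic about its reference state with stiffness ``k_perp`` orthogonal
    to the A->B transition direction u (in 3N space) and ``k_par`` along it.
    Decoupling the two stiffnesses lets a modest barrier coexist with
    protein-like (~1 A) thermal fluctuations: isotropic basins soft enough
    to give a few-kT barrier over a 5 A transition would fluctuate more
    than the transition amplitude itself.
    """

    def __init__(self, a, b, k_par: float, k_perp: float, beta_star: float):
        self.a, self.b = a, b
        self.k_par, self.k_perp, self.beta_star = k_par, k_perp, beta_star
        u = (b - a).ravel()
        self.u = u / np.linalg.norm(u)

    def _basin(self, x: np.ndarray, ref: np.ndarray):
        d = (x - ref).ravel()
        t = float(d @ self.u)
        v = 0.5 * self.k_perp * (d @ d) + 0.5 * (self.k_par - self.k_perp) * t * t
        g = self.k_perp * d + (self.k_par - self.k_perp) * t * self.u
        return v, g.reshape(x.shape)

    def basin_energies(self, x: np.ndarray) -> np.ndarray:
        return np.array([self._basin(x, self.a)[0], self._basin(x, self.b)[0]])

    def energy(self, x: np.ndarray) -> float:
        v = self.basin_energies(x)
        vmin = v.min()
        return float(vmin - np.log(np.exp(-self.beta_star * (v - vmin)).sum()) / self.beta_star)

    def __call__(self, x: np.ndarray):
        va, ga = self._basin(x, self.a)
        vb, gb = self._basin(x, self.b)
        w = softmax(-self.beta_star * np.array([va, vb]))
        force = -(w[0] * ga + w[1] * gb)
        vmin = min(va, vb)
        energy = vmin - np.log(np.exp(-self.beta_star * (np.array([va, vb]) - vmin)).sum()) / self.beta_star
        return float(energy), force


def make_two_state_system(
    n_beads: int = 30,
    target_rmsd: float = 5.0,
    barrier: float = 6.0,
    seed: int = 0,
    temperature: float = 300.0,
    stiffness_perp: float = 5.0,
) -> TwoStateSystem:
    """Build a two-state bead chain with requested endpoint RMSD and barrier.

    ``state_a`` is a helical chain, ``state_b`` interpolates toward an
    extended chain, with the interpolation factor root-solved so the fitted
    C-alpha RMSD matches ``target_rmsd`` (within 5%).  The longitudinal
    spring constant of the double-basin mixture is calibrated numerically so
    the barrier along the connecting line equals ``barrier`` (in kB*T units
    at ``temperature``) within 10%; ``stiffness_perp`` (kJ/mol/A^2) sets the
    orthogonal stiffness, i.e. the ~sqrt(3 kT / k_perp) thermal fluctuation
    amplitude per bead.

    Raises
    ------
    ConstructionError
        If the requested RMSD is unreachable for this chain length.
    """
    if n_beads < 4:
        raise ParameterError("n_beads must be >= 4")
    a = _helix_chain(n_beads)
    b_full = _extended_chain(n_beads)
    # root-solve the interpolation factor for the fitted endpoint RMSD

    def rmsd_at(alpha: float) -> float:
        msd, _ = fitted_msd(a, a + alpha * (b_full - a))
        return float(np.sqrt(msd))

    hi = 2.0
    if rmsd_at(hi) < target_rmsd:
        raise ConstructionError(
            f"target RMSD {target_rmsd} A unreachable with {n_beads} beads "
            f"(max ~{rmsd_at(hi):.2f} A)"
        )
    alpha = brentq(lambda al: rmsd_at(al) - target_rmsd, 1e-9, hi, xtol=1e-12)
    b = a + alpha * (b_full - a)

    barrier_kj = barrier * KB * temperature
    beta_star = 10.0 / barrier_kj
    t_grid = np.linspace(0.0, 1.0, 801)

    def barrier_at(k_par: float) -> float:
        f = _DoubleBasinForce(a, b, k_par, stiffness_perp, beta_star)
        vals = np.array([f.energy(a + t * (b - a)) for t in t_grid])
        return float(vals.max() - min(vals[0], vals[-1]))

    s2 = ((b - a) ** 2).sum()
    k0 = 8.0 * barrier_kj / s2  # harmonic-midpoint estimate seeds the bracket
    k_par = brentq(lambda kk: barrier_at(kk) - barrier_kj, 0.05 * k0, 20.0 * k0, xtol=1e-14)
    force = _DoubleBasinForce(a, b, k_par, stiffness_perp, beta_star)

    meta = {
        "k_par": k_par,
        "k_perp": stiffness_perp,
        "beta_star": beta_star,
        "alpha": alpha,
        "achieved_rmsd": rmsd_at(alpha),
        "achieved_barrier_kj": barrier_at(k_par),
        "barrier_target_kj": barrier_kj,
        "temperature": temperature,
        "seed": seed,
    }
    return TwoStateSystem(
        state_a=Structure(a.copy()),
        state_b=Structure(b.copy()),
        force_provider=force,
        target_rmsd=target_rmsd,
        barrier_kt=barrier,
        metadata=meta,
    )


def make_interpolated_trajectory(
    a: Structure, b: Structure, n_frames: int, noise_sigma: float = 0.0, seed: int = 0
) -> Trajectory:
    """Linear cartesian interpolation from a to b with optional jitter.

    With ``noise_sigma`` 0 the endpoints are exact and consecutive spacing
    is uniform; otherwise isotropic Gaussian noise of that width (A) is
    added independently to every frame.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if a.n_atoms != b.n_atoms:
        raise DimensionError("endpoint structures differ in atom count")
    t = np.linspace(0.0, 1.0, n_frames)[:, None, None]
    coords = a.coords[None] * (1 - t) + b.coords[None] * t
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + noise_sigma * rng.standard_normal(coords.shape)
    return Trajectory.from_coords(coords, a)


class DoubleWell1D:
    """V(x) = barrier * (x^2 - 1)^2 + tilt * x, minima near +-1 (kJ/mol).

    The well free-energy difference at temperature T is exposed through a
    Boltzmann quadrature oracle (divider at the barrier top).
    """

    ndim = 1

    def __init__(self, barrier: float = 12.0, tilt: float = 1.0):
        if barrier <= 0:
            raise ParameterError("barrier must be > 0")
        self.barrier = barrier
        self.tilt = tilt
        self.start = np.array([-1.0])
        self.minima = [
            minimize_scalar(self._v, bounds=(-2.0, 0.0), method="bounded").x,
            minimize_scalar(self._v, bounds=(0.0, 2.0), method="bounded").x,
        ]
        self.divider = minimize_scalar(
            lambda x: -self._v(x), bounds=(self.minima[0], self.minima[1]), method="bounded"
        ).x

    def _v(self, x: float) -> float:
        return self.barrier * (x * x - 1.0) ** 2 + self.tilt * x

    def value(self, x) -> float:
        x = np.atleast_1d(x)[0]
        return self._v(x)

    def grad(self, x) -> np.ndarray:
        x = np.atleast_1d(x)[0]
        return np.array([4.0 * self.barrier * x * (x * x - 1.0) + self.tilt])

    def free_energy_difference(self, kt: float, lo: float = -3.0, hi: float = 3.0) -> float:
        """F(right well) - F(left well) via numeric Boltzmann integrals (kJ/mol)."""
        za, _ = quad(lambda x: np.exp(-self._v(x) / kt), lo, self.divider, limit=200)
        zb, _ = quad(lambda x: np.exp(-self._v(x) / kt), self.divider, hi, limit=200)
        return float(-kt * np.log(zb / za))

    def barrier_from_left(self) -> float:
        """V(divider) - V(left minimum), kJ/mol."""
        return self._v(self.divider) - self._v(self.minima[0])


class CurvedValley2D:
    """V(s, z) = P(s) + 0.5 * kappa * (z - g(s))^2 with a curved valley g.

    ``g(s) = z0 + amp * sin(pi s)``; the 1-D profile P(s) =
    barrier * sin^2(pi s) + tilt * s has minima at s = 0 and 1.  Evaluated
    on its own valley curve the potential returns P exactly.
    """

    ndim = 2

    def __init__(self, barrier: float = 10.0, tilt: float = -2.0,
                 kappa: float = 40.0, z0: float = 1.0, amp: float = 0.6):
        self.barrier, self.tilt, self.kappa = barrier, tilt, kappa
        self.z0, self.amp = z0, amp
        self.start = np.array([0.02, z0])

    def valley(self, s):
        return self.z0 + self.amp * np.sin(np.pi * np.asarray(s))

    def profile(self, s):
        s = np.asarray(s)
        return self.barrier * np.sin(np.pi * s) ** 2 + self.tilt * s

    def value(self, x) -> float:
        s, z = np.atleast_1d(x)
        return float(self.profile(s) + 0.5 * self.kappa * (z - self.valley(s)) ** 2)

    def grad(self, x) -> np.ndarray:
        s, z = np.atleast_1d(x)
        dP = self.barrier * np.pi * np.sin(2 * np.pi * s) + self.tilt
        dg = self.amp * np.pi * np.cos(np.pi * s)
        dz = self.kappa * (z - self.valley(s))
        return np.array([dP - dz * dg, dz])


@dataclass
class ThreeStepProfile:
    """A constructed 25-bin MFEP profile with known step decomposition."""

    profile: MFEPProfile
    expected_steps: list
    barriers: tuple
    final_drop: float


def _three_step_profile(barriers=(13.8, 7.5), intermediate: float = 2.0,
                        final_drop: float = 3.4) -> ThreeStepProfile:
    b1, b2 = barriers
    nodes = [(0, 0.0), (5, b1), (10, intermediate), (15, intermediate + b2), (24, -final_drop)]
    F = np.empty(25)
    for (i0, f0), (i1, f1) in zip(nodes[:-1], nodes[1:]):
        F[i0:i1 + 1] = np.linspace(f0, f1, i1 - i0 + 1)
    centers = (np.arange(25) + 0.5) / 25.0
    prof = MFEPProfile(bin_centers=centers, z_at_min=None, F=F)
    expected = [(b1, intermediate), (b2, -final_drop - intermediate)]
    return ThreeStepProfile(profile=prof, expected_steps=expected,
                            barriers=barriers, final_drop=final_drop)


def make_analytic_fes(kind: str, **params):
    """Analytic landscapes with known minima, barriers and valley curves.

    ``kind`` is one of ``double_well_1d`` (-> :class:`DoubleWell1D`),
    ``curved_valley_2d`` (-> :class:`CurvedValley2D`) or
    ``three_step_profile`` (-> :class:`ThreeStepProfile`).
    """
    if kind == "double_well_1d":
        return DoubleWell1D(**params)
    if kind == "curved_valley_2d":
        return CurvedValley2D(**params)
    if kind == "three_step_profile":
        return _three_step_profile(**params)
    raise ParameterError(f"unknown analytic landscape kind '{kind}'")


@dataclass
class AR1Series:
    """Stationary AR(1) draw with its analytic statistics.

    ``tau = -1/ln(rho)`` is the autocorrelation time; ``sem_analytic`` is
    the true standard error of the sample mean,
    sigma * sqrt((1 + rho) / ((1 - rho) n)).
    """

    values: np.ndarray
    rho: float
    sigma: float
    tau: float
    sem_analytic: float


def make_ar1_series(n: int, rho: float, sigma: float, seed: int = 0) -> AR1Series:
    """Stationary AR(1): x_{t+1} = rho x_t + sqrt(1-rho^2) sigma eps_t."""
    if abs(rho) >= 1:
        raise ParameterError("|rho| must be < 1")
    if n < 100:
        raise ParameterError("n must be >= 100")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal()
    c = np.sqrt(1.0 - rho * rho) * sigma
    eps = rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + c * eps[t - 1]
    tau = np.inf if rho <= 0 else -1.0 / np.log(rho)
    sem = sigma * np.sqrt((1.0 + rho) / ((1.0 - rho) * n))
    return AR1Series(values=x, rho=rho, sigma=sigma,
                     tau=float(tau if rho > 0 else 0.0), sem_analytic=float(sem))
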