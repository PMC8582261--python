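"""One-config end-to-end run: fixture -> EDS -> path -> wT-metaD -> MFEP.

Mirrors the composite protocol on the desk-scale two-state fixture: build
the system, sample the target basin for the essential subspace, ratchet an
EDS trajectory from the inactive to the active state, select reference
frames with the 0.44-0.60 A spacing band, run well-tempered metadynamics on
the (s, z) path CVs, reconstruct the free-energy surface and extract the
25-bin MFEP with its step barriers.  A fixed seed makes the whole chain
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .core import select_all
from .dynamics import LangevinParams, sample_basin
from .essential import EDSParams, covariance_modes, run_eds
from .fes import extract_mfep, fes_from_bias, profile_barriers, rate_determining_barrier
from .fixtures import make_two_state_system
from .metad import MetaDParams, PathCVSystem, run_wt_metad
from .pathcv import select_frames, smooth_trajectory, validate_path
from .core import Trajectory

DEFAULT_CONFIG = {
    "system": {"n_beads": 30, "target_rmsd": 5.0, "barrier_kt": 6.0},
    "subspace": {"basin_steps": 4000, "save_every": 20, "n_modes": 40},
    "eds": {"n_steps": 10000, "step_size": 0.02, "friction": 5.0, "temperature": 300.0},
    "path": {"lo": 0.44, "hi": 0.60, "smooth_window": 200},
    # sigma_s follows the production recipe's ~2%-of-N width; wall_k is the
    # production value scaled by the bead/atom-count ratio so per-atom wall
    # forces match (see docs/methods.md); dt 0.002 ps as in production MD.
    "metad": {
        "n_steps": 400000,
        "dt": 0.002,
        "friction": 5.0,
        "stride": 250,
        "w0": 0.5,
        "gamma": 30.0,
        "sigma_s": 0.4,
        "sigma_z": 0.1,
        "z_max": 3.0,
        "wall_k": 200.0,
        "temperature": 300.0,
        "log_stride": 10,
    },
    "fes": {"n_s": 101, "n_z": 81, "z_lo": 0.0, "z_hi": 4.0, "n_bins": 25},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) for k, v in base.items()}
    for section, values in (override or {}).items():
        out.setdefault(section, {}).update(values)
    return out


def run_pipeline(config: dict | None = None, seed: int = 0) -> dict:
    """Run the full composite protocol; returns a dict of all artifacts.

    Keys: ``system``, ``subspace``, ``eds_traj``, ``path``, ``path_report``,
    ``cv_log``, ``bias``, ``fes``, ``mfep``, ``steps``,
    ``rate_determining_barrier``.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    sys_cfg, eds_cfg, md_cfg = cfg["system"], cfg["eds"], cfg["metad"]

    system = make_two_state_system(
        n_beads=sys_cfg["n_beads"],
        target_rmsd=sys_cfg["target_rmsd"],
        barrier=sys_cfg["barrier_kt"],
        seed=seed,
    )
    sel = select_all(system.state_a)

    # essential subspace of the target (active) state from a basin run
    sub_cfg = cfg["subspace"]
    rng = np.random.default_rng(seed + 1)
    lp = LangevinParams(dt=eds_cfg["step_size"], friction=eds_cfg["friction"],
                        temperature=eds_cfg["temperature"])
    snaps = sample_basin(system.state_b.coords, system.force_provider,
                         sub_cfg["basin_steps"], sub_cfg["save_every"], lp, rng)
    basin_traj = Trajectory.from_coords(snaps, system.state_b)
    subspace = covariance_modes(basin_traj, sel)

    eds_params = EDSParams(
        subspace_size=min(sub_cfg["n_modes"], subspace.n_modes),
        selection=sel,
        step_size=eds_cfg["step_size"],
        friction=eds_cfg["friction"],
        temperature=eds_cfg["temperature"],
        seed=seed + 2,
    )
    eds_traj = run_eds(system.state_a, system.state_b, subspace,
                       eds_cfg["n_steps"], system.force_provider, eds_params)

    smoothed = smooth_trajectory(eds_traj, cfg["path"]["smooth_window"])
    path = select_frames(smoothed, system.state_b,
                         (cfg["path"]["lo"], cfg["path"]["hi"]), sel)
    report = validate_path(path, system.state_b, (cfg["path"]["lo"], cfg["path"]["hi"]))

    metad_params = MetaDParams(
        temperature=md_cfg["temperature"],
        gamma=md_cfg["gamma"],
        w0=md_cfg["w0"],
        stride=md_cfg["stride"],
        sigma_s=md_cfg["sigma_s"],
        sigma_z=md_cfg["sigma_z"],
        z_max=md_cfg["z_max"],
        wall_k=md_cfg["wall_k"],
        seed=seed + 3,
    )
    mol = PathCVSystem(system.force_provider, path, system.state_a)
    cv_log, bias = run_wt_metad(
        mol, metad_params, md_cfg["n_steps"],
        langevin=LangevinParams(dt=md_cfg["dt"], friction=md_cfg["friction"],
                                temperature=md_cfg["temperature"]),
        log_stride=md_cfg["log_stride"],
    )

    fes_cfg = cfg["fes"]
    s_grid = np.linspace(0.0, 1.0, fes_cfg["n_s"])
    z_grid = np.linspace(fes_cfg["z_lo"], fes_cfg["z_hi"], fes_cfg["n_z"])
    fes = fes_from_bias(bias, s_grid, z_grid, n_path_frames=path.n_frames)
    mfep = extract_mfep(fes, n_bins=fes_cfg["n_bins"])
    steps = profile_barriers(mfep)

    return {
        "system": system,
        "subspace": subspace,
        "eds_traj": eds_traj,
        "path": path,
        "path_report": report,
        "cv_log": cv_log,
        "bias": bias,
        "fes": fes,
        "mfep": mfep,
        "steps": steps,
        "rate_determining_barrier": rate_determining_barrier(steps),
        "config": cfg,
        "seed": seed,
    }
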