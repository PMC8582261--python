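"""Drive the inactive state to the active state with EDS.

A short unbiased run around the target builds the essential subspace (top
principal components of the fluctuation covariance); the EDS ratchet then
accepts Langevin trials that reduce the fitted RMSD to the target and
projects rejected ones back in the subspace, so the RMSD trace can only
decrease.
"""

import numpy as np

import pathmetad as pm
from pathmetad.core import Trajectory
from pathmetad.dynamics import LangevinParams, sample_basin

system = pm.make_two_state_system(30, 5.0, 6.0, seed=1)
sel = pm.select_all(system.state_a)

rng = np.random.default_rng(2)
snaps = sample_basin(system.state_b.coords, system.force_provider,
                     4000, 20, LangevinParams(dt=0.02, friction=5.0), rng)
subspace = pm.covariance_modes(Trajectory.from_coords(snaps, system.state_b), sel)
cumvar = subspace.cumulative_variance()
print(f"essential subspace: {subspace.n_modes} modes; "
      f"top 10 carry {cumvar[9] * 100:.1f}% of the fluctuation variance")

params = pm.EDSParams(subspace_size=40, selection=sel, seed=3)
traj = pm.run_eds(system.state_a, system.state_b, subspace, 10_000,
                  system.force_provider, params)

r = traj.rmsd_to_target
for step in (0, 1000, 3000, 5000, 8000, 10_000):
    print(f"step {step:>6d}: RMSD to target = {r[step]:.3f} A")
print(f"acceptance fraction: {traj.accepted_fraction:.2f}")
print(f"monotone non-increasing trace: {bool(np.all(np.diff(r) <= 1e-6))}")
# The trace ratchets from 5 A to well under 0.5 A: the transition path the
# reference-path CVs will be built from.
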