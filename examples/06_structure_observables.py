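"""Structural observables along a transition: RMSD traces, SASA, H-bonds,
backbone dihedrals, pairwise RMSD maps.

These are the descriptors used to characterise what changes along an
activation path (loop opening, motif flips, solvent exposure).
"""

import numpy as np

import pathmetad as pm
from pathmetad.analysis import dihedral_angle
from pathmetad.core import AtomSelection, Structure, Trajectory

system = pm.make_two_state_system(30, 5.0, 6.0, seed=1)
traj = pm.make_interpolated_trajectory(system.state_a, system.state_b, 9)

# per-element RMSD trace: fit on the element, RMSD over the element
loop = pm.ElementDefinition("mobile-segment", [(10, 20)])
trace = pm.element_rmsd_trace(traj, system.state_b, loop, mode="calpha")
print("segment RMSD to target along the path (A):",
      " ".join(f"{r:.2f}" for r in trace))

# SASA of the same segment grows as the chain extends
sel = pm.select_residues(system.state_a, range(10, 21), "mobile-segment")
for label, state in [("state A", system.state_a), ("state B", system.state_b)]:
    area = pm.sasa_shrake_rupley(state, sel)
    print(f"{label} segment SASA: {area:7.1f} A^2")

# hydrogen bond: ideal water dimer geometry
dimer = Structure(
    np.array([[0, 0, 0], [0.96, 0, 0], [-0.32, 0.91, 0],
              [2.8, 0, 0], [3.12, 0.91, 0], [3.12, -0.91, 0]], dtype=float),
    atom_names=np.array(["O", "H1", "H2", "O", "H1", "H2"], dtype=object),
    residue_ids=np.array([1, 1, 1, 2, 2, 2]),
    elements=np.array(["O", "H", "H", "O", "H", "H"], dtype=object),
)
n = pm.hbond_count(dimer, AtomSelection(np.array([0])), AtomSelection(np.array([3])))
print(f"water dimer at 2.8 A O-O: {n} hydrogen bond (0.35 nm / 30 deg criterion)")

# a dihedral from four points (IUPAC sign convention)
pts = np.array([[0, 0, 0], [1.5, 0, 0], [2.0, 1.4, 0], [1.6, 2.0, 1.1]], dtype=float)
print(f"example dihedral: {dihedral_angle(*pts):.1f} deg")

# pairwise RMSD map between path frames and basin-B snapshots
short = Trajectory.from_coords(traj.coords[:4], system.state_a)
M, closest = pm.pairwise_rmsd_map(short, traj, pm.select_all(system.state_a))
print("closest path frame per early frame:", closest.tolist())
# Row argmins identify which reference frame each snapshot resembles most.
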