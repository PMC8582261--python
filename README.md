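# pathmetad

A desk-scale toolkit for mapping two-state conformational transitions —
the kind of inactive → active switch seen in protein kinases — with the
composite enhanced-sampling protocol:

1. **Essential dynamics sampling (EDS)** ratchets a Langevin trajectory
   from the initial to the target structure: a trial step is accepted when
   the fitted RMSD to the target decreases, otherwise it is projected back
   inside the essential subspace (the top principal components of the
   fluctuation covariance).
2. **Path collective variables** are built from N reference frames selected
   from the EDS path so consecutive fitted Cα RMSDs stay within a
   0.44–0.60 Å band and frames are topologically consecutive:

       s(R) = Σⱼ j·exp(−λ dⱼ²) / Σⱼ exp(−λ dⱼ²)         (progress along the path)
       z(R) = −(1/λ)·ln Σⱼ exp(−λ dⱼ²)                  (distance from the path)

   with dⱼ² the per-atom mean squared displacement to frame j after optimal
   superposition, λ = 2.3 / ⟨MSD between consecutive frames⟩ (≈ 9.2 Å⁻² for
   0.5 Å spacing), and ŝ = (s−1)/(N−1) ∈ [0, 1] for cross-system comparison.
3. **Well-tempered metadynamics** biases (s, z): Gaussian hills of initial
   height 0.5 kJ/mol every 500 steps, heights damped by
   exp(−V/k_B ΔT) with bias factor γ = 30, and a one-sided harmonic wall on
   z. The converged bias gives the free energy, F = −γ/(γ−1)·V.
4. **Downstream analysis**: the minimum free energy path (MFEP) as the
   per-ŝ-bin (25 bins) minimum over z of F(ŝ, z) with its step-barrier
   decomposition; statistical errors by constant-final-bias reweighting
   plus block averaging (block sizes 10–500, step 10); GROMOS clustering,
   per-element RMSD traces, H-bond counts, Shrake–Rupley SASA, backbone
   dihedrals and pairwise RMSD maps.

Everything runs on synthetic, fully deterministic fixtures — a two-state
bead chain with a calibrated double-basin potential, analytic free-energy
landscapes with known minima/valleys/barriers, AR(1) series with known
statistics — so the whole protocol is testable on one CPU in minutes with
no external data.

## Worked example

Recovering a known 1-D double-well free energy with well-tempered
metadynamics (`examples/04_double_well_metadynamics.py`):

```
oracle: dF = 3.790 kJ/mol, barrier = 14.062 kJ/mol
2000 hills deposited; heights damped 0.500 -> 0.220 kJ/mol
recovered: dF = 3.920 kJ/mol (error 0.05 kT)
recovered: barrier = 13.863 kJ/mol (error 0.08 kT)
```

The "oracle" line is the ground truth from Boltzmann quadrature on the
analytic potential; the "recovered" lines come from the final metadynamics
bias via F = −γ/(γ−1)·V. Both agree to a small fraction of k_BT, i.e. the
engine reconstructs free-energy differences and barriers within thermal
noise.

Building path CVs from a transition trajectory
(`examples/03_path_cvs.py`):

```
kept 12 of 201 frames
lambda = 11.12 A^-2   spacing_ok=True topology_ok=True
state A  : s_hat =  0.009   z = -0.0090 A^2
state B  : s_hat =  0.995   z = -0.0054 A^2
perturbed midpoint (0.5 A jitter): s_hat = 0.536   z = 0.633 A^2
```

ŝ runs 0 → 1 from the inactive to the active endpoint; z stays ≈ 0 for
on-path configurations and grows for displacements orthogonal to the path.

The other scripts in `examples/` cover the two-state fixture, the EDS
ratchet, the full pipeline with MFEP + error analysis, and the structural
observables. A thin CLI wraps the same calls
(`pathmetad pipeline --seed 1`, `pathmetad mfep --hills HILLS.tsv ...`).

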