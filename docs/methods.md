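# Methods

This note records the models, conventions and numerical choices behind
`pathmetad`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Coordinates, units and superposition

Coordinates are ångström throughout; energies kJ/mol internally
(kcal/mol = kJ/mol / 4.184 for reported surfaces and profiles); time ps;
mass amu; k_B = 0.0083145 kJ mol⁻¹ K⁻¹. The conversion
1 kJ/mol/(amu·Å) = 100 Å/ps² enters the propagators as a single constant.

All "fitted" quantities use Kabsch superposition: the optimal proper
rotation from the SVD of the cross-covariance of centred point sets, with
the reflection corrected through the smallest singular direction. RMSD is
evaluated through the singular-value identity
(|P|² + |Q|² − 2(σ₁+σ₂±σ₃))/n, which costs no explicit rotation but
cancels to ~10⁻⁶ Å on identical structures — tests of exact-zero RMSD use
that tolerance. A batched variant superposes one probe against a stack of
frames in a single vectorised SVD; it is the inner loop of path-CV
evaluation.

**MSD convention.** The mean squared displacement is **per-atom averaged**
(Å²), not summed. This makes the path-CV smoothing parameter λ carry Å⁻²
and reproduces the λ ≈ 9.2 Å⁻² regime for ~0.5 Å frame spacing through
λ = 2.3/⟨MSD⟩. Users comparing against PLUMED should check which
normalisation their path files assume.

## Path collective variables

For N ordered reference frames X₁..X_N and dⱼ²(X) the fitted per-atom MSD
to frame j (each frame aligned independently),

    s = Σⱼ j·e^(−λ dⱼ²) / Σⱼ e^(−λ dⱼ²),   z = −(1/λ)·ln Σⱼ e^(−λ dⱼ²),

with ŝ = (s−1)/(N−1). Evaluation goes through log-sum-exp/softmax so large
λ·d² never overflow. Any affine rescaling of s is absorbed by ŝ, so MFEP
results do not depend on the index origin.

Gradients (needed to propagate bias forces onto atoms) use the envelope
theorem: at the optimal superposition the derivatives through the rotation
and translation vanish, leaving ∇dⱼ² = (2/M)(x_c − Rⱼᵀ f_cj). They are
verified against central finite differences in the tests.

**Frame selection** is a greedy forward scan: keep the first frame, then
every frame whose fitted RMSD from the last kept frame first enters the
[0.44, 0.60] Å band *and* that is strictly closer to the target than all
previously kept frames (topological consecutiveness). The scan terminates
at the trajectory frame closest to the target whenever the spacing band
allows (append if in band; replace the last kept frame if the tail is
shorter than the band and the merged interval stays in band); otherwise
the path ends at the closest approach compatible with the band, so
`validate_path` always passes on `select_frames` output.

Selecting frames from a *finely saved* stochastic trajectory is
ill-posed: thermal jitter folds the path back on itself inside each basin,
so frames far apart in index are close in space and s becomes
ill-conditioned. `smooth_trajectory` (boxcar average, pipeline default
window 200 steps = 0.4 ps) selects frames from the mean drift instead —
the same effect a production protocol gets by saving coordinates every
1 ps.

## Essential dynamics sampling

The essential subspace is built from the covariance of fitted fluctuations
(frames iteratively aligned to their mean, three passes), eigendecomposed
with a deterministic sign convention (first non-negligible component
positive). Projections onto the subspace use the raw (unfitted)
fluctuation against the stored mean; the toy potentials are tethered in
space, so no extra alignment is needed.

One EDS step is one BAOAB Langevin step producing a trial: accepted if the
fitted RMSD to the target (over the driver's selection) does not increase;
otherwise the trial's displacement is corrected radially in the retained
subspace so its subspace distance to the target returns to the previous
value, the orthogonal-complement motion is kept, and the outward radial
velocity component is removed. Because the orthogonal motion can still
raise the full RMSD, a final guard holds the previous coordinates (with
the corrected velocity) in that case — this makes the RMSD-to-target trace
monotonically non-increasing by construction, which is the observable
contract of the method. Driver defaults (dt 0.02 ps, friction 5 ps⁻¹,
mass 12 amu, 300 K) let the ratchet cover a 5 Å transition in well under
10⁴ steps on the packaged fixture; the limiting timescale is the
deterministic relaxation m·γ/k of the soft transition mode.

## Well-tempered metadynamics

Hills are Gaussians in (s, z) — raw s units, not ŝ: a width of 2.0 on the
ŝ axis would flatten the landscape, while 2 frames out of ~100 resolves
multi-basin profiles. Heights follow h = w₀·exp(−V_hills/k_B ΔT),
ΔT = (γ−1)T, evaluated on the hill bias only (the wall never damps
deposits). Hills are truncated at 6σ. The wall is one-sided harmonic in z:
½·k_wall·(z−z_max)² above z_max only. Defaults: w₀ = 0.5 kJ/mol, stride
500 steps, γ = 30, σ_s = 2.0, σ_z = 0.005 Å², z_max = 3.0 Å²,
k_wall = 10⁴ kJ mol⁻¹ Å⁻⁴ — the production protocol values.

The engine runs either on an analytic CV-space potential (1-D or 2-D; the
coordinates are the CVs) or on a toy molecular system through the path-CV
chain rule, F_bias = −(∂V/∂s)∇s − (∂V/∂z)∇z. Free energies come from the
final bias, F = −γ/(γ−1)·V_hills, min-shifted to zero, in kcal/mol.

**Desk-scale settings for the 30-bead pipeline** (config values, not
library defaults): dt = 2 fs for the metadynamics stage — the z wall is a
stiff constraint and larger steps integrate it unstably; k_wall scaled to
200 kJ mol⁻¹ Å⁻⁴ because per-atom z-gradients scale as 1/M, so the 30-bead
chain feels ~50× larger per-atom wall forces than a ~300-residue kinase at
equal k_wall; σ_s = 0.4 keeps the ~2%-of-N width ratio for the toy's
~12-frame path; σ_z = 0.1 Å² so a few hundred hills can tile the z range.
The pipeline's 4·10⁵ steps give one full crossing plus partial filling of
the product basin — enough to demonstrate the machinery, *not* a converged
free-energy estimate (see Limitations).

## MFEP and error analysis

The ŝ axis is divided into 25 equal bins; per bin the grid node with the
lowest F (over z and within-bin ŝ) defines the profile, referenced to the
first bin. An empty bin is a hard error (refine the grid), never silently
interpolated. Step decomposition: local minima/maxima of the 25-point
profile; each ascending segment contributes (barrier, net ΔF) =
(next max − preceding min, next min − preceding min); the rate-determining
step is the largest barrier.

Reweighting assumes a constant bias equal to the final one:
wᵢ ∝ exp(+V_final(sᵢ, zᵢ)/k_BT), max-shifted before exponentiation,
normalised to one. Block averaging discretises ŝ into the same 25 bins
and, per block size B (10–500 step 10), propagates the standard error of
the per-block weighted population fraction into a free-energy error,
err_F = k_BT·SEM(p)/mean(p); only occupied bins enter the mean (missing,
not zero). The per-bin error is propagated on probability — whether it
should act on probability or directly on F is not standardised; the k_BT
σ_p/p form is adopted and documented. The underlying blocked standard
error of a plain weighted series is exposed (`blocked_sem`) and is what
AR(1)/i.i.d. calibration checks use: for AR(1) the plateau matches
σ·√((1+ρ)/(1−ρ)/n) within sampling error, and for i.i.d. input the scan is
flat.

## Synthetic fixtures

The two-state system is a 30-bead Cα-like chain: a helix (2.3 Å radius,
100° twist, 1.5 Å rise) and a partially extended copy, with the
interpolation factor root-solved so the fitted endpoint RMSD hits the
request (default 5.0 Å) exactly. The potential is an exponential mixing of
two **anisotropic** harmonic-network basins: stiffness k_perp
(default 5 kJ mol⁻¹ Å⁻²) orthogonal to the A→B direction in 3N space and a
soft longitudinal constant calibrated by root-finding so the barrier along
the connecting line matches the request (default 6 k_BT) within 10%.
Anisotropy is essential: isotropic basins soft enough for a few-k_BT
barrier over 5 Å would fluctuate by ~11 Å per bead, drowning the
transition; with k_perp = 5 the chain fluctuates ~1 Å per bead
(protein-like) and z lives in the 1–3 Å² range the wall assumes. Both
endpoints are exact minima of the mixed potential (|∇V| ≤ 10⁻⁶). The
potential is tethered to absolute coordinates (not rotation-invariant) —
acceptable for fixtures, and it keeps the minima exact.

What the fixtures do **not** emulate: solvent and friction heterogeneity,
bonded-topology stiffness (hence the large 20 fs EDS step), rugged
multi-minimum landscapes, and any rotational diffusion. Passing tests
therefore demonstrate the correctness of the machinery — CV evaluation,
bias accounting, path construction, error propagation — not the
convergence behaviour on real solvated proteins.

Analytic landscapes: a quartic double well (tilt parameter sets a known
ΔF via Boltzmann quadrature), a curved-valley 2-D surface
V = P(ŝ) + ½κ(z − g(ŝ))² whose MFEP is g and whose profile is P exactly,
and a piecewise-linear 25-bin three-step profile with constructed barriers
(defaults 13.8 and 7.5 kcal/mol with a 3.4 kcal/mol net drop, the scale of
kinase activation steps). AR(1) series carry their analytic
autocorrelation time τ = −1/ln ρ and standard error of the mean.
All generators are pure functions of (parameters, seed).

## Determinism

Every stochastic component draws from `numpy.random.Generator(PCG64)`
seeded explicitly; the pipeline derives stage seeds as seed+1..seed+3.
Identical (config, seed) reproduce trajectories, hills and logs
bit-for-bit on the same platform/BLAS.

## Known limitations

- The pipeline's reconstructed barrier is a single-crossing estimate; a
  converged profile needs many recrossings (production runs use 10⁷–10⁸
  steps).
- The path-CV s is only meaningful while the reference path does not fold
  back within ~λ^(−1/2) of itself; `smooth_trajectory` mitigates but does
  not eliminate this for very noisy inputs.
- H-bond detection infers donor hydrogens by distance (≤1.25 Å), not by
  topology; structures without explicit hydrogens raise a topology error.
- `superpose_kabsch` and friends assume equal atom weights; no
  mass-weighting.
- PDB output goes through biotite's writer (fixed columns, no insertion
  codes); occupancy/B-factor round-trips only via the path-PDB writer.
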