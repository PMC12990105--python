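# Methods

## Path collective variables

Both path CV flavours express progress `s` and deviation `z` as exponential
averages over an ordered milestone sequence of length N:

    s = Σᵢ i·wᵢ / Σᵢ wᵢ ,   z = −(1/λ) ln Σᵢ wᵢ

with weights `wᵢ = exp(−λ·mᵢ)` over a per-milestone metric `mᵢ`.

* **RPATH** — milestones are full reference conformations and
  `mᵢ = R[X−Xᵢ]`, the superposed RMSD (λ in nm⁻¹). The exponent is linear
  in R. Because some engine conventions use mean-square deviations, the
  `squared` flag of `PathDefinition` switches to `mᵢ = R²` (λ then in
  nm⁻²); the default is the linear form.
* **EPATH** — a conformation is the point
  `M = (RMSD_inactive, RMSD_active)` and `mᵢ = d(M, Mᵢ)²`, the squared
  Euclidean distance to the milestone tuple (λ in nm⁻²). Both RMSDs use
  the same align/measure C-alpha selection.

All weight sums are evaluated max-shifted (log-sum-exp), so results are
exact to machine precision for arbitrarily large λ; `s` then converges to
the nearest-milestone index and `z` to the minimum metric. No tie-break is
needed at finite λ: `s` is a smooth weighted mean, never an argmax.

### Arched milestone placement

`build_arched_path` draws milestones on a quadratic Bézier from
M₁ = (0, D) to M_N = (D, 0), where D is the superposed RMSD between the two
end-state structures. The `arch` parameter (dimensionless, default 0.3) is
defined by the curve **apex**: the t = ½ point of the Bézier sits at
`((1+arch)·D/2, (1+arch)·D/2)` on the plane diagonal, which places the
control point at `((1+2·arch)·D/2, …)`. Parameterizing by the apex rather
than the control point makes `arch` directly readable as the fractional
bulge of the path above the straight chord (arch = 0 recovers the straight
two-reference difference coordinate as a limiting case) and gives the exact
midpoint identity used in the tests: D = 1, N = 3, arch = 0.3 puts the
middle milestone at (0.65, 0.65).

Interior milestones are placed at equal arc length. The arc-length map is
computed on a 20001-point parameter grid and inverted by linear
interpolation; the node parameters are then symmetrized,
`t ← (t + (1 − t_reversed))/2`, so the construction is exactly invariant
under swapping the two RMSD axes and reversing milestone order. Every
milestone satisfies `rmsd_inactive + rmsd_active ≥ D` for arch ≥ 0 (the
curve bows away from the origin, avoiding the improbable region where both
RMSDs are small). Default N = 8.

### Choosing λ

`suggest_lambda` targets the sweet spot between a step-like and a
washed-out projection: `λ = ln 2 / ⟨m⟩` over consecutive milestone metric
gaps, so the weight at a neighbouring milestone is ≈ ½. That smoothness is
right for *biasing*, but it delocalizes `s`: a frame sitting exactly on an
end milestone projects to s ≈ 1.4 on an equally spaced path. For
*analysis* projections — assigning frames to path intervals, defining
basin windows in s — the package therefore uses `analysis_lambda`, a
4× sharper value (neighbour weight 1/16) that pins end-milestone frames to
within ≈ 0.06 of the end index while keeping interior interpolation
smooth. The projection CLI applies the sharper value by default
(`--no-sharpen` disables this).

### Superposition

`rmsd_superposed` performs the least-squares rigid fit on the *align* atom
set (scipy's Kabsch-style `Rotation.align_vectors`, proper rotations only —
the determinant correction preserves chirality) and evaluates the RMSD over
the *measure* set after that fit. Fits with fewer than 3 align atoms or a
(near-)collinear align set (second singular value ≤ 1e-10 × the first) are
rejected as geometry errors rather than silently returning one of the
degenerate optima. Periodic-boundary effects are not handled; inputs are
assumed whole.

### Restraints

Intermediate metastable traps are handled by harmonic restraints on
auxiliary CVs (microswitch distances) gated by a progress window:
`E = w(s)·κ·(x−x₀)²` with `w(s)` a cosine-taper bump — identically zero
outside `[s_lo, s_hi]`, one on the inner plateau, half-cosine ramps of
width `taper` (default 0.25 in s units) at the edges. Windows are meant to
exclude the end states, so end-point stabilities are untouched. Loose
one-sided walls `κ·max(0, z−z_max)²` keep the sampling near the path. The
numeric κ, window and wall values are system-specific inputs, not package
defaults.

## Engine input emission

`write_epath_plumed` emits the EPATH CV as explicit arithmetic expressions
(`CUSTOM` actions using only exp/log — plus step and cos for the restraint
bumps) over two `RMSD` variables, with milestone constants embedded as
literals at 6 significant digits and λ at 10. Emission is byte-deterministic
for identical inputs. Reference PDBs follow the engine convention:
occupancy = alignment weight, B-factor = displacement (measure) weight,
coordinates in Å. The tests validate the emitted expressions with an
independent symbolic interpreter against the CV evaluated on the path *as
emitted* (i.e. rebuilt from the 6-digit literals), so expression fidelity
is not conflated with literal rounding.

## Reweighting

Static final-bias reweighting: per-frame weights `w = exp(ΣV_bias/kT)` from
the recorded bias columns (the time-dependent normalization correction of
on-the-fly biasing schemes is out of scope; on a convergence-focused
replica the bias is quasi-static). Free energies are `−kT ln` of the
weighted histogram, min-shifted to 0; empty bins are flagged unobserved
(NaN), never assigned zero energy. The bias sum is max-shifted before
exponentiation — free energies are invariant under constant bias shifts, so
this is exact, and with zero bias the estimator reduces *exactly* to the
plain histogram. Rows with non-finite bias or CV values are rejected and
counted. Which bias columns enter is always an explicit argument.

Basin ΔG traces use cumulative reweighted populations of two disjoint
s-windows, `ΔG(t) = −kT ln(W_active(≤t)/W_inactive(≤t))`, reported from the
first time both basins are populated. Default windows are s ∈ [1, 1.5] and
[N−0.5, N]; a 2-D basin definition (e.g. RMSD_active < 0.1 nm) can be
expressed by windowing on an RMSD column instead. Replica averaging is the
pointwise mean with the n−1 sample standard deviation. Uncertainty of a
single run uses a block bootstrap (default 20 contiguous blocks, 200
resamples) to respect serial correlation. kT defaults to 310 K
(0.6160 kcal/mol) and is configurable everywhere.

## Clustering and entropy

`gromos_cluster` implements the greedy neighbor-count rule: on the pairwise
superposed RMSD matrix of a selection, repeatedly take the unassigned frame
with the most unassigned neighbors within the cutoff (inclusive, ties to
the lowest frame index) as the next cluster center. Clusters are relabelled
by decreasing population (equal sizes by center index), making reruns
bit-identical. The default cutoff is 0.14 nm (1.4 Å on secondary-structure
C-alphas, the value appropriate at receptor scale); toy systems are smaller
and analyses there use a proportionally smaller cutoff. The cutoff is
always recorded in output metadata.

`entropy_profile` partitions frames by progress interval, clusters each
interval *independently*, and reports the Shannon entropy
`S/k_B = −Σ pᵢ ln pᵢ` of the interval's cluster populations (0·ln 0 := 0;
populations renormalized with a warning if they do not sum to 1 within
1e-9). Per-interval clustering (rather than one global clustering split by
interval) matches the per-interval question — how diverse is the ensemble
*here* — and is the documented, deliberate choice. Entropy is bounded by
ln(number of clusters), and merging clusters can only lower it.

## Synthetic systems

The generators exist so that every stage has a ground truth:

* **End states** — an ideal α-helical C-alpha trace (0.23 nm radius,
  0.15 nm rise, 100°/residue; 30 atoms) perturbed once by seeded Gaussian
  noise (0.02 nm), with the terminal 40% rotated 60° about a hinge for the
  active state. The same noise realization enters both states, so zero
  bend gives zero RMSD, and the construction validates that the end-state
  RMSD exceeds 5× the noise.
* **Transition trajectories** — linear interpolation after superposing the
  end states, plus `detour·sin(πt)` times a fixed random unit-RMS
  displacement field (pushing mid-path frames away from *both* references,
  emulating the entropic intermediate basin) and Gaussian noise enveloped
  by `sin(πt)`. The envelope encodes the physical picture that end basins
  are tight and the middle diffuse; first/last frames are exactly the end
  states.
* **Biased samples** — Metropolis Monte Carlo (chosen over Langevin
  because the stationary law is exact, which the reweighting tests rely
  on) on `U(x) = barrier·((x/a)²−1)²` (default barrier 5 kcal/mol, wells
  at ±1) with bias `V = −c·U(clamp(x, ±1.5a))`: proportional inside the
  well region, constant beyond, the way a deposited sampling bias fills
  basins while the landscape's confining walls survive (c = 1 flattens
  wells and barrier without unbinding the walker). Default c = 0.8,
  proposal width 0.25, burn-in 1000. The 2-D form adds a harmonic
  transverse coordinate (k = 2 kcal/mol).

What the toys do **not** emulate: membrane/solvent environments, the
dynamics of bias deposition, microswitch coupling, or the true
dimensionality of receptor conformational space. Passing tests demonstrate
the correctness of the mathematics and the qualitative entropy/convergence
phenomenology, not receptor-scale free energies — the real systems'
headline numbers (e.g. an activation ΔG near 18 kcal/mol) require the full
membrane-embedded MD data and are out of scope by design.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately small scale,
chosen as the smallest sizes at which each property is sharply testable:
oracle comparisons on ~10³ random CV instances; superposition against
10⁵-sample rotation searches (plus a Nelder-Mead polish of the best sample,
since raw random search resolves the optimum only to ~10⁻³ nm); 2×10⁵
Metropolis samples for reweighting recovery (statistical agreement within
3 block-bootstrap standard errors of quadrature truth); 60-frame toy
trajectories for the end-to-end entropy profile. Milestone extraction
searches subsequences exhaustively up to 20 frames and falls back to an
equal-arc-length heuristic above. COLVAR parsing keeps the last occurrence
of duplicated time stamps (restart overlaps) and requires interior restart
headers to match the first.

## Known limitations

* RPATH serialization stores milestone structures in a companion
  multi-MODEL PDB; only EPATH configs round-trip through the plain-text
  config alone.
* Binary trajectory formats are not read natively; any reader producing an
  (n_frames, n_atoms, 3) nm array can feed the same `Trajectory` contract.
* The reweighting assumes the recorded bias columns are the complete bias
  acting on the sampled ensemble.
* At large deviations from the path, RMSD-plane coordinates degenerate
  (many distinct structures share one (RMSD, RMSD) point); `z` walls exist
  precisely to keep sampling where the description is informative.
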