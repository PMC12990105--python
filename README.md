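# epathcv

Path collective variables (CVs) for large conformational transitions —
built for the activation of class A G-protein-coupled receptors (GPCRs),
usable for any two-state transition with known end-point structures.

Enhanced-sampling free-energy calculations of transitions such as GPCR
activation need a one-dimensional *progress* coordinate. The classic
structure-based path CV (here **RPATH**) requires a curated sequence of
intermediate reference structures, which must be guessed, refined and
re-refined per system. The **Euclidean path CV (EPATH)** removes that
burden: a conformation X is encoded by just two numbers — its C-alpha RMSDs
to the inactive and active reference structures — and the path is a
sequence of milestones M_i drawn directly in that (RMSD_inactive,
RMSD_active) plane. Only the two end milestones, (0, D) and (D, 0) with D
the inter-end-state RMSD, are tied to real structures; the interior
milestones are placed on a slightly arched curve above the diagonal.

With d(M, M_i) the Euclidean distance in the RMSD plane, the progress and
deviation variables are

    s(M) = Σᵢ i·exp(−λ d(M,Mᵢ)²) / Σᵢ exp(−λ d(M,Mᵢ)²)
    z(M) = −(1/λ) ln Σᵢ exp(−λ d(M,Mᵢ)²)

(for RPATH the metric is the superposed RMSD R[X−Xᵢ], with the exponent
linear in R). λ sets the smoothness of the projection; the package suggests
a value in the sweet spot between step-like and washed-out behavior.

The package covers the full workflow around that definition:

* **structures** — PDB/GRO I/O (nm internally), C-alpha selection,
  Kabsch superposition RMSD with separate align/measure atom sets,
  milestone extraction from transition trajectories;
* **path_cv** — EPATH/RPATH s and z, arched-path construction, λ
  selection, windowed harmonic restraints (microswitch guidance that
  vanishes at the end states) and deviation walls;
* **plumed_io** — COLVAR table parsing, PLUMED reference PDBs
  (occupancy/beta weight columns), deterministic emission of the EPATH CV
  as an explicit PLUMED expression;
* **reweighting** — bias reweighting to 1D/2D free-energy surfaces, basin
  ΔG convergence traces, replica averaging, block-bootstrap errors;
* **clustering** — gromos conformational clustering and Shannon-entropy
  profiles of conformational heterogeneity along the path;
* **synthetic** — toy two-state systems, transition trajectories and
  Metropolis-sampled double-well data with analytically known answers;
* **cli** — an `epathcv` command exposing each stage.

## Worked example

```sh
epathcv synth endstates --seed 7 -o toy
epathcv synth trajectory --inactive toy/inactive.pdb --active toy/active.pdb \
    --n-frames 30 --noise 0.05 --detour 0.15 --seed 7 -o toy
epathcv build-path --inactive toy/inactive.pdb --active toy/active.pdb \
    --n 6 --arch 0.3 -o path
epathcv project --traj toy/trajectory.pdb --path-config path/path_config.txt \
    --inactive toy/inactive.pdb --active toy/active.pdb -o proj
epathcv entropy --traj toy/trajectory.pdb --colvar proj/COLVAR_projected \
    --edges 1,2,3,4,5,6 --cutoff 0.05 -o ent
```

`build-path` prints

```
end-state RMSD D = 0.3521 nm; lambda = 62.7892 1/nm^2; 6 milestones -> path/path_config.txt
```

— the toy end states are 0.35 nm apart, and the six milestones arch above
the diagonal of the RMSD plane. `entropy` prints

```
entropy per interval: 0.500 1.792 1.946 1.946 0.500 -> ent/entropy_profile.txt
```

— the Shannon entropy (in units of k_B) of the gromos cluster populations
per path interval: near zero at the two terminal intervals, where the
ensemble is pinned to the well-defined end structures, and high in the
middle, where the transition crosses a structurally diverse intermediate
region. The same library calls are available in Python (`import epathcv`).

The equivalent PLUMED input for running the biased simulation itself is
produced by `epathcv emit-plumed`.

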