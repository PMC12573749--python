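# flextop

Undirected exploration of protein binding pockets with
**flexible-topology (FT) particles** — simulation particles whose
nonbonded identity (partial charge *q*, Lennard-Jones radius *σ*, well
depth *ε*) is itself dynamical — plus the grid-based analysis stack
used to turn the resulting pseudo-molecular templates into screening
queries.

**Who it is for.**  Computational chemists and structural
bioinformaticians who want to learn the *preferences* of a binding
pocket — where charge is rewarded, how much volume is available, what
shape and electrostatic pattern a good ligand should present — without
enumerating candidate molecules.  The package provides the particle
simulator, the analysis metrics, desk-scale synthetic fixtures, and a
command-line pipeline.

## The model

A set of *N* FT particles evolves inside a rigid-or-restrained pocket.
Positions follow Langevin dynamics; attributes follow Brownian dynamics
on the same energy surface:

* FT–environment nonbonded energy (per particle *i*, environment atom *j*):

  V = Σ_j 4 ε_ij [ (σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶ ] + k_e q_i q_j / r_ij,

  with σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_i ε_j) and
  k_e = 138.935456 (kJ/mol)·nm·e⁻².
* Supercharged FT–FT electrostatics V = g Σ k_e q_i q_j / r_ij
  (g = 1.5 by default) promotes juxtaposition of opposite charges and
  keeps molecular dipoles ligand-like; a steric FT–FT LJ term prevents
  pair collapse.
* AttrForce V = A·f(σ)(ε−¼)² + B·f(σ)(q−¼)², f(σ) = 1/(1+e^{C(σ−0.3)}),
  A = 941.5, B = 275.3: confines (q, ε) for small radii the way real
  atom parameters are distributed (small atoms are hydrogens).
* A continuity force k(r−d)² (d = 0.25 nm, k = 10⁴ kJ/mol/nm²) bridges
  disconnected components of the particle cutoff graph so the swarm
  stays one contiguous entity.
* A flat-bottom centroid restraint (d₀ = 0.9 nm, k = 10³ kJ/mol/nm²)
  keeps particles in the pocket.

The integrator clamps attributes to their bounds
(q ∈ [−0.5, 0.5], σ ∈ [0.20, 0.36] nm, ε ∈ [0.03, 1.50] kJ/mol),
constrains Σq to zero and caps the charge variance at
S_max = 0.08 e², which bounds the rms particle charge at
√S_max ≈ 0.283 e.

Analysis grids (δ = 1 Å) provide atomic densities, electrostatic
potentials in units of k_e, shape overlap
O_S = 1 − Σ|x−y|/(Σx+Σy), clipped-EP electrostatic overlap
O_E = 2Σxy/(Σ|x|+Σ|y|), volume / polar surface area / globularity
descriptors, polar-interaction detection (Σ q_i q_j/r_ij < −0.3 e²/nm)
and KMeans clustering of EP maps.  Filtered frames export as TRIPOS
mol2 queries (artificial carbon atoms + the FT charges) for downstream
shape/charge screening tools.

See `docs/methods.md` for assumptions, parameter rationale and known
limitations.

## Worked example

Run the full pipeline on the built-in toy pocket (a spherical cavity of
frozen LJ atoms with one fixed −1.0 e site on the wall, standing in for
a carboxylate-bearing pocket):

```bash
flextop demo --seed 7 --n-particles 8 --out-dir demo_out -k 5
```

which prints (about half a minute):

```
INFO wrote demo_out/system.yaml
INFO run done: 200 frames, max |sum q| dev 9.96e-14, max S_q 0.0800, bound violations 0
INFO wrote demo_out/frames.csv
INFO wrote demo_out/summary.csv and demo_out/descriptors.csv
INFO wrote demo_out/cluster_summary.csv
INFO exported 2 mol2 queries to demo_out
```

The run log already shows the integrator contract: across all 34,000
steps the charge sum stayed at zero to 1e-13, the charge variance never
exceeded S_max = 0.08 e², and no attribute left its bounds.
`descriptors.csv` holds per-frame grid descriptors and the
polar-interaction check against the anionic site; its first rows:

```
 frame  step  volume   psa  globularity  polar_contact  polar_proxy
     0   100    42.0  29.0     0.215         True          -1.643
     1   200    45.0  37.0     0.211         True          -1.779
```

`volume` (Å³) and `psa` (Å²) are grid counts at δ = 1 Å; `polar_proxy`
is Σ q_i q_j/r_ij in e²/nm between the FT swarm and the wall site — far
below the −0.3 threshold, i.e. the particles nearest the anionic site
have developed complementary positive charge.  `summary.csv` aggregates
the best shape/electrostatic overlaps of all frames against the three
built-in reference pseudoligands, and `query_*.mol2` contains the
frames that passed the query filter (polar contact present and
globularity < 0.2), ready for a screening tool that accepts mol2 with
existing charges.

Individual stages are available as `flextop init | simulate | analyze |
cluster | export-query`, all driven by a YAML config
(`system / forces / schedule / output` sections; every force parameter
overridable).  The same functionality is importable
(`flextop.run_schedule`, `flextop.best_overlap_summary`, …).

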