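# Methods

## The model

`flextop` simulates *flexible-topology* (FT) particles: ligand-surrogate
particles whose nonbonded parameters — partial charge q [e],
Lennard-Jones radius σ [nm] and well depth ε [kJ/mol] — are dynamical
variables that evolve under gradients of the potential energy, alongside
the particle positions.  Watching a swarm of such particles relax inside
a binding pocket reveals what charges, sizes and positions the pocket
prefers; the resulting pseudo-molecular templates are then gridded,
scored against reference ligands, clustered, and exported as mol2
queries for shape/charge screening.

Internal units are nm, kJ/mol, e, ps and amu, in which the Coulomb
prefactor is k_e = 138.935456 (kJ/mol)·nm·e⁻² and
1 amu·nm²/ps² = 1 kJ/mol, so the integrator needs no unit conversions.
Grid analysis is Å-based (spacing, volumes, PSA, dipoles), with the
nm→Å factor exactly 10.

### Energy terms

* **FT–environment nonbonded.**  For FT particle i and environment atom
  j: V = 4 ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶] + k_e q_i q_j / r, with
  Lorentz–Berthelot mixing (σ_ij arithmetic mean, ε_ij geometric mean).
  Analytic gradients are returned for positions and for (q_i, σ_i,
  ε_i); the ε-gradient uses ∂V_LJ/∂ε_i = V_LJ/(2ε_i), exact for the
  geometric mixing rule.
* **Supercharged FT–FT electrostatics.**  V = g Σ k_e q_i q_j / r_ij
  over FT pairs.  The factor g > 1 promotes juxtaposition of opposite
  charges — standing in for the polarization pattern of covalently
  bonded atoms — and suppresses the unphysically large molecular
  dipoles that appear when FT–FT electrostatics is removed.  Modes:
  `physical` (full sum times g), `repulsive` (only q_i q_j > 0 pairs,
  for ablation studies), `off`.  Default g = 1.5.
* **FT–FT Lennard-Jones** (same mixing rules) prevents the collapse of
  oppositely charged pairs under the supercharged attraction.  It is a
  toggleable term (`ft_ft_lj`), on by default.
* **Continuity force.**  The cutoff graph places edges between FT pairs
  with r ≤ d = 0.25 nm (closed inequality).  If the graph has more than
  one connected component, a harmonic attraction E = k (r − d)² with
  k = 10000 kJ/mol/nm² bridges components.  Default pairing rule:
  for each component other than the largest, a single term on the
  closest pair connecting it to its nearest other component, with
  duplicate pairs counted once.  This choice keeps the energy
  *continuous* at the connect/disconnect boundary (the activating pair
  has r = d, zero energy).  The alternative `pairing="all"` (every
  inter-component pair) pulls fragments together much harder, but the
  energy jumps discontinuously by Σ k (r_ij − d)² the moment a
  component detaches; in a small vacuum system that impulse pumps
  enough kinetic energy to destabilize the run, so it is not the
  default.
* **Attribute restraint (AttrForce).**
  V = A f(σ)(ε − 0.25)² + B f(σ)(q − 0.25)², f(σ) = 1/(1 + e^{C(σ−0.3)}),
  A = 941.5, B = 275.3 (constants fit elsewhere against the attribute
  statistics of a large set of CGenFF-parametrized molecules and
  adopted as given).  For σ below 0.3 nm the restraint confines q and ε
  near 0.25 — mimicking the fact that the only small-radius atoms in
  real molecules are hydrogens with small positive charges — and
  switches off as σ grows past 0.3 nm.  C sets the switching steepness;
  the default C = 200 nm⁻¹ gives a ~0.02 nm switching width — fast on
  the scale of the σ range — and is exposed in config.  The exponent
  argument is clipped at ±500 to avoid overflow for out-of-range σ.
* **Flat-bottom centroid restraint.**
  V = ½ k_CBF H(d − d₀)(d − d₀)² per particle, d the distance to the
  binding-site centroid, d₀ = 0.9 nm, k_CBF = 1000 kJ/mol/nm².
  H(0) = 0 (measure-zero choice, documented).
* **Environment position restraints** (group-wise harmonic, used in the
  restrained first heating stage): 400 kcal/mol/nm² on "backbone",
  40 kcal/mol/nm² on "other", converted at 1 kcal = 4.184 kJ.

Nonbonded terms use no distance cutoff by default (exact summation,
appropriate for desk-scale systems); a minimum-image convention with a
configurable cutoff activates when a periodic box is set.

### Integrator

Positions evolve by Langevin dynamics with a BAOAB splitting (friction
default 1 ps⁻¹, step 2 fs, particle mass 12 amu); attributes evolve by
overdamped Brownian dynamics,
a ← a − μ_a Δt ∂V/∂a + √(2 k_B T μ_a Δt)·ξ, which avoids ascribing
velocities to the attributes and makes bound enforcement trivial.  One
force evaluation is performed per step: the closing velocity half-kick
uses the fresh force at the new positions, which is cached for the next
step's opening half-kick, and the same evaluation's attribute gradients
drive the Brownian update.  The cached force is therefore evaluated at
the pre-update attributes — a first-order splitting consistent with the
overall scheme.

**Attribute mobilities.**  Defaults are μ_q = 2·10⁻⁴ e²/(kJ/mol)/ps,
μ_σ = 5·10⁻⁵ nm²/(kJ/mol)/ps, μ_ε = 5·10⁻⁵ (kJ/mol)/(kJ/mol/ps)⁻¹.
They were chosen so that attributes relax roughly an order of magnitude
more slowly than positions: against the attribute-restraint curvature
(2B f ≈ 550 kJ/mol/e² for q, 2A f ≈ 1900 for ε) the relaxation time
1/(μκ) is ~10 ps versus ~1 ps for positions.  Much larger mobilities
make the attribute noise non-adiabatic relative to position relaxation:
σ then inflates the LJ core of deeply bound (supercharged) pairs faster
than the pair can re-equilibrate, pumping kinetic energy into the
system.  Mobilities are configuration parameters, not claims about any
other implementation.

**Charge constraints.**  After every attribute step a constraint sweep
runs: clamp to the bound box (q ∈ [−0.5, 0.5], σ ∈ [0.20, 0.36],
ε ∈ [0.03, 1.50]), uniform shift of the charges to the target sum
(default 0 e), variance cap (deviations from the mean scaled by
√(S_max/S_q) when S_q = (1/n)Σ(q_i − q̄)² exceeds S_max = 0.08 e²).
The three charge constraints are convex sets with nonempty
intersection, so the sweep is repeated (alternating projections) until
all hold to 10⁻¹³; in practice one sweep suffices except when the clamp
truncates an outlier charge.  With a zero target sum the cap bounds the
rms charge at √S_max = 0.2828 e.

**Minimization** is projected gradient descent with a backtracking line
search on either the attribute block or the position block; the largest
single-coordinate move per iteration is capped at 0.02 (nm or attribute
units) so that steep-overlap gradients cannot tunnel a particle through
a repulsive wall.  The stopping criterion is an rms-gradient threshold
(default 100, max 1000 steps).  Energy never increases across accepted
steps.

### Initialization

Positions are drawn from an isotropic Gaussian centred on the
binding-site centroid with per-axis standard deviation 0.9 nm ("width"
read as σ of the Gaussian — the most common convention).  A trial is
accepted if it is (1) ≥ 0.20 nm from every environment atom, (2)
≥ 0.15 nm from every placed FT particle and (3) ≤ 0.25 nm from the
nearest placed FT particle (vacuous for the first particle; any other
reading deadlocks).  10000 trials per attempt, up to 10 restarts,
then a hard failure advising to free more space or use fewer particles.
Initial attributes: q ~ U[−0.01, 0.01], ε ~ U[0.03, 1.50], σ = 0.20.

### Schedule

The standard protocol is: optional restrained stage at 10 K, heating
ladder 10/20/50/100/150/200/250/300 K truncated at the production
temperature, then the production stage, saving every `save_every`-th
frame of the production stage only.  The full-scale protocol uses 10⁵
steps per heating stage and 10⁶ production steps saving every 2000th
frame; the desk-scale toy default is 10³ per heating stage and 10⁴
production steps, i.e. a 1:100 scale-down chosen to keep a full
pipeline run in seconds while preserving the staging structure.

## Grid analysis

Densities and electrostatic potentials (EP) are sampled on a cubic
lattice with spacing δ = 1.0 Å by default.  A grid point is occupied by
a particle when its distance to the particle centre is < σ/2 (σ the
particle diameter in Å; for FT frames the LJ σ parameter converted to
Å).  The EP is Σ q_i/r in *units of k_e*, so the clipped ternary map
V_EPᶜ uses the threshold 0.3 in those units (+1 above 0.3, −1 below
−0.3), matching the 0.3k isovalue convention used for EP surfaces.
Shape overlap O_S = 1 − Σ|x−y| / (Σx + Σy) ∈ [0,1] on binary
densities; electrostatic overlap O_E = 2Σxy / (Σ|x| + Σ|y|) ∈ [−1,1]
on clipped maps.  Compared maps always share one grid: the union
bounding box of both particle sets padded by 2 Å, origin snapped onto
the δ lattice anchored at (0,0,0).

Descriptors: volume = occupied cells × δ³; polar surface area = number
of unoccupied cells 6-face-adjacent to a polar cell (occupied by an
atom with |q| > 0.3) × δ²; globularity = volume / volume of the sphere
whose diameter is the largest interparticle distance (needs ≥ 2
particles).  The 6-face adjacency is a documented choice (the
neighborhood is not otherwise pinned down) and configurable in code.
The dipole is |Σ q_i (r_i − r̄)| about the geometric centroid; for
zero-net-charge sets it is reference-independent.

Polar interactions between an FT group and a residue/site use the
prefactor-free proxy Σ q_i q_j / r_ij [e²/nm], flagged when strictly
below −0.3; frame subsampling for polar statistics defaults to every
10th frame.  Donor/acceptor roles are a charge-sign heuristic on the
dominant pair (positive site partner = donor) — a stand-in for manual
inspection, and labelled as such.

Clustering partitions flattened clipped-EP vectors with KMeans
(k-means++, single init, fixed seed); each cluster is represented by
the member frame nearest the cluster mean, and occupancies always sum
to the frame count.

## The toy pocket

The test fixture is a rigid spherical cavity in a filled medium: two
(default) concentric shells of frozen LJ atoms (σ 0.3 nm, ε 0.5 kJ/mol,
q 0, ~0.2 nm lateral spacing) so that the outside of the pocket is
occupied, as the protein interior is around a real binding site.
Optional fixed charged sites (the standard configuration has one
−1.0 e carboxylate-like site just inside the wall) and solvent-tagged
mobile particles can be added.  The default cavity radius packs the
requested particle count at ~0.03 nm³ per particle — the free volume
liberated by deleting roughly a dozen waters, i.e. ligand-like heavy
atom density in a slightly roomy pocket — plus one LJ contact distance
for the wall shell.  Because the toy wall is a thin shell with vacuum
beyond it (unlike the infinite medium of a real system), the fixture
re-samples the placement until the whole initial cluster sits inside
the cavity.

What the toy does *not* emulate: protein flexibility, solvent and
counterions, chemical detail of the pocket lining, and realistic
energy dissipation into an extended environment.  Tests passing on the
toy demonstrate the mechanics of the method — force correctness,
constraint enforcement, charge complementarity, pipeline integrity —
not its performance on real receptors.

Reference "pseudoligands" for the metric tests are three hand-coded
charged-particle sets (compact polar, roomy apolar, elongated
zwitterion-like) spanning distinct volume/PSA/globularity/dipole
regimes.  They are synthetic stand-ins, not derived from any crystal
structure.

## Numerical choices and edge cases

* Cutoff-graph edges use r ≤ d (closed); H(0) = 0 in the flat-bottom
  restraint.  Both measure-zero choices.
* Coincident interacting particles raise a singular-geometry error;
  non-finite forces or gradients raise an integration error naming the
  particle and stage.
* Ternary-map overlaps between two all-zero maps are undefined (error)
  at the metric level; the batch overlap summary scores such pairs as
  0 (no electrostatic signature, uncorrelated).
* Solvent-removal ties are broken by stable input order.
* One configuration seed drives placement, initial attributes and the
  thermostats through independent named RNG streams, so trajectories
  are bitwise reproducible and changing the number of draws in one
  stage does not perturb another.

## Known limitations

* **Instantaneous-graph connectivity.**  The continuity force holds
  bridging pairs *at* the cutoff distance (its energy minimum is at
  r = d), so a bridged pair thermally hovers around d and the strict
  instantaneous cutoff graph flickers between one and several
  components; outward pushes (LJ contact distances of grown particles,
  like-charge repulsion) bias bridges slightly outside d.  Moreover the
  attribute restraint makes σ > 0.3 nm free-energetically attractive
  for particles whose charge deviates from +0.25 (negative particles
  in particular), and such particles have LJ contact distances above
  the 0.25 nm cutoff.  Consequently, at production temperatures the
  fraction of frames forming a single instantaneous cutoff-graph
  component is well below 1 even though the swarm remains one physical
  cluster — bottleneck link distances stay within a few hundredths of
  a nm of the cutoff.  The particles stay contiguous in the mechanical
  sense (the continuity force re-joins any detaching fragment within a
  few steps); the strict graph criterion is a much harder target and is
  reported honestly by the test suite.
* Brownian attributes and Langevin positions share one temperature.
* The energy model is vacuum electrostatics without polarization,
  reaction field or Ewald summation.
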