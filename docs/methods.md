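# Methods

This note documents the models and procedures implemented in `remdock`,
the parameter choices that matter, and the limits of what the synthetic
test bed demonstrates.

## Pocket construction

The binding cavity is represented by its *negative image*: the lattice
points of a cubic box (edge 20 Å, spacing 2 Å, centred on the user-supplied
binding-site center) that survive four filters, applied in this order:

1. **Receptor distance.** Keep points whose distance to the nearest
   receptor atom lies in [2.5, 4.5] Å — close enough to hug the cavity
   wall, far enough to leave room for a ligand atom. Predicted receptor
   models use a 2.0 Å lower cutoff (distorted pockets are tighter), and if
   fewer than 10 points survive this filter, the remaining filters are
   skipped so enough points remain to seed initial poses.
2. **Singleton removal.** Drop points with fewer than 3 adjacent surviving
   points. *Adjacent* is the 26-neighbourhood at one lattice step; with a
   6-neighbourhood and 2 Å spacing a "≥ 3 neighbours" rule would wipe out
   legitimate points at cavity mouths. The filter runs in a single pass
   over the survivors of filter 1 (not to convergence).
3. **Solvent exposure.** From each point, rays are cast along ±x, ±y, ±z;
   a ray is blocked when it passes within a receptor atom's van der Waals
   radius. Points with fewer than K = 4 of 6 rays blocked are considered
   solvent-exposed and dropped. The rule is deterministic, cheap, and
   configurable; a buried cavity point blocks all six rays, a point in a
   hemispherical cup five.
4. **Ligand radius.** Keep points within the ligand radius (centroid to
   farthest atom) of the *original* binding-site center — the box center is
   not recentred after the earlier filters.

Lattice convention: ⌈edge/spacing⌉ + 1 points per axis, symmetric about the
center (11³ = 1331 at the defaults, with the center itself a node). When
spacing does not divide the edge, the lattice spans the smallest covering
multiple of the spacing.

## Graph matching

A node is a (ligand heavy atom, grid point) pair; nodes i, j are edged when
|d_ij^ligand − d_ij^pocket| < 0.25 × n_edge, where n_edge counts edges
already accepted (1 for the first, 2 for the second, …). The growing
tolerance makes acceptance order-dependent, so the order is pinned down:
nodes are enumerated ligand-atom-major / grid-point-minor; every compatible
node pair (edge test at n_edge = 1) seeds a clique; the clique is extended
one node at a time by the first node in enumeration order whose edges to
all current members pass at the running counter, each accepted edge
advancing the counter by one. The counter is **per clique**, not global —
a global counter would make later cliques arbitrarily sloppy. Cliques of
3–10 nodes are kept (3 points suffice for superposition), capped at 2000
for tractability, and duplicates under node-set equality are merged.

Each clique's atom↔point correspondence is solved by Kabsch superposition
(SVD with the reflection branch corrected to a proper rotation) and applied
to the whole ligand. Collinear cliques have no unique rotation and are
skipped. Initial replica poses are the lowest-energy superpositions below
the 10⁶ kcal/mol viability cutoff; in predicted-receptor mode the 20 best
are also flipped 180° about a random axis through their centroid (pocket
distortion can leave graph matching oriented backwards); random rotations
of existing poses pad the list to 5N when needed, and random placements at
the pocket centroid are the last resort.

## Force field

E = Σ_prot Σ_lig [w₁(A/d¹² − B/d⁶) + w₂ q_iq_j/(4d)]
  + w₃ Σ_k d_k + w₄ Σ ½(d−μ)²/σ² + w₅ Σ_{i<j} (C/s¹² − D/s⁶)

* **12-6 terms.** A = εR¹², B = 2εR⁶ with R = r_i + r_j and ε = √(ε_iε_j),
  so the pair minimum is −ε at d = R. Radii and well depths come from an
  AMBER99-style table keyed by atom type with element-symbol fallback;
  unresolvable types are a hard error.
* **Coulomb.** Implemented literally as q_iq_j/(4d) — a distance-dependent
  dielectric absorbed into the denominator, with *no* 332 kcal·Å/(mol·e²)
  conversion factor. The weights were tuned against this literal form, so
  inserting the constant would change the balance of the terms. Charges
  must be pre-assigned in the ligand MOL2; receptors read from plain PDB
  carry zero charge, which simply disables their Coulomb contribution.
* **Pocket restraint.** Σ_k d_k over grid points, d_k the minimum distance
  from any ligand atom to point k: an Å-valued pull of the ligand onto the
  negative image. The mixed units of the total are accepted as-is; the
  dimensionless weights make the scale internal.
* **Distance profile.** Optional per-pair Gaussian restraints (μ, σ) read
  from a TSV; σ ≤ 0 is rejected at parse time since σ² divides the term.
  An empty profile contributes zero.
* **Intra-ligand 12-6.** Pairs at bond-graph distance ≤ 2 (1-2 bonded and
  1-3 angle pairs) are excluded — they would otherwise sit deep in the
  repulsive singularity; 1-4 pairs count at full weight. Weight w₅ is 1 in
  flexible docking and 0 in rigid docking, where the term is constant.

Weights: experimental receptors use (1, 1, 0, 0, w₅) in all five runs;
predicted models run w₁ ∈ {0.001, 0.004, 0.02, 0.1, 1} with w₂ = 1,
w₃ = 1 − w₁, w₄ = 0.01, trading steric strictness against the pocket pull
across runs to accommodate different degrees of pocket distortion.

A 12 Å truncation cutoff (no switching) is applied to the inter-molecular
pair sums; on the bundled fixtures it changes totals by < 0.01 kcal/mol
against the uncut evaluation, which the tests verify. `cutoff=None`
disables it.

## REMC protocol

Temperatures follow the geometric ladder T_i = T_min(T_max/T_min)^((i−1)/(N−1)),
T_min = 1, T_max = 60, in kcal/mol with the Boltzmann constant folded in
(k ≡ 1). Each local move translates the ligand by a uniform vector in
[−0.2, 0.2] Å per axis, then rotates it about a uniformly oriented axis
through its centroid by a uniform angle in [−3°, 3°]; the axis direction is
sampled via θ = 2πr₁, φ = cos⁻¹(2r₂ − 1), which is uniform on the sphere.
Flexible docking then twists one uniformly chosen rotatable bond by a
uniform angle in [−180°, 180°], rotating the smaller side of the bond
partition. Rotatable bonds are the single, non-terminal, non-ring bonds of
the MOL2 bond table (terminal and ring "single" bonds are excluded because
twisting them is a null move or breaks ring geometry); an explicit list can
override the detection. A flexible input whose intra-ligand 12-6 energy
exceeds 100 kcal/mol is first relaxed by 500 torsion-only Metropolis steps
at T_max.

Moves are accepted with min{1, exp(−ΔE/kT)}. After every 200 local moves
per replica, one sweep of adjacent-pair swaps runs, alternating even/odd
pair offsets between sweeps; a swap is accepted with
min{1, exp((E_j − E_i)(1/kT_j − 1/kT_i))} and exchanges poses (temperatures
stay with the ladder slots — equivalent to exchanging temperatures, but
decoy bookkeeping by temperature slot stays trivial). Decoys are recorded
every 20 local moves from the 4 lowest-temperature replicas; the initial
pose is not recorded. The default protocol (5 runs × 4 replicas × 100
sweeps × 200/20) therefore collects exactly 20,000 decoys. All randomness
derives from one master seed through spawned per-replica streams, so a
fixed seed reproduces a decoy set bit for bit.

## Selection and evaluation

Decoys are clustered by max-neighbour peeling on in-frame heavy-atom RMSD
(cutoff 2.0 Å, configurable): the decoy with the most neighbours within the
cutoff is removed together with them as one cluster, repeatedly, so the
clusters partition the decoy set. No re-superposition is applied — all
decoys share the receptor frame, and superposing them would erase exactly
the positional differences that matter for docking. The representative is
the cluster medoid (a physically realized pose, unlike a coordinate
average); clusters rank by multiplicity, ties by lower representative
energy. A scorer hook (callable, higher = better) can replace the
multiplicity ranking, standing in for empirical affinity functions that
outperform clustering on high-quality experimental receptors.

Symmetry-corrected RMSD minimizes the in-frame RMSD over all element- and
bond-preserving automorphisms of the heavy-atom graph (found via VF2);
tests verify it against exhaustive label permutations on small ligands.
The evaluator requires predicted and reference poses in a common receptor
frame; superposing a *predicted receptor model* onto the reference receptor
first is out of scope. Hydrogens are excluded from all metrics. Contact
precision/recall/F1 use residues with any heavy-atom pair closer than
r_i + r_j + 0.5 Å (strict inequality, as at the other thresholds — the
8 Å binding-site error bound and the 2/5 Å success cutoffs); metrics with
an undefined denominator are reported as `None`, never as 0.

## Synthetic test bed

The fixture generators build: spherical cages and hemispherical cups of
carbon-like pseudo-atoms (known cavity centers, for pocket tests), alkane
chains (known rotatable bonds), aromatic rings (known automorphism groups),
rigid asymmetric polyatoms, and complete docking cases. A docking case
plants an 8-atom rigid asymmetric ligand at the origin and molds a
180-atom receptor shell around it at the van der Waals contact optimum
(2 × 1.908 Å from the nearest ligand atom along each of 180 spherical
directions), creating a deep shape-specific funnel with negative native
energy. Charges are small seeded values summing to zero, so the van der
Waals terms dominate.

What this does **not** emulate: real protein chemistry (typed atoms,
hydrogen bonding, charged residues), pocket distortion of predicted
models, competing cavities, ligand strain, or solvation. Passing the
recovery test shows the machinery — pocket imaging, matching, sampling,
clustering — converges to a planted global minimum under the stated
protocol; it does not certify accuracy on real complexes, which in the
underlying method depends on dataset-scale benchmarking outside this
package's scope.

Reported problem sizes: the end-to-end tests and the acceptance script run
1 run × 8 replicas × 20 swap epochs per case (32,000 energy evaluations,
800 decoys) over five seeds — chosen as the smallest schedule at which
recovery is stable on the synthetic cases.

## Numerical choices and limitations

* Coordinates are Å throughout; atom indices 1-based, matching PDB/MOL2.
* PDB reading keeps the alphabetically first altloc and the first model;
  hydrogens are retained if present and, when parameterized, participate
  in the energy (a heavy-atom-only switch exists on the energy model).
* Kabsch superposition refuses < 3 points or collinear sets.
* Ties in clustering break toward lower decoy index (peeling pick) and
  lower representative energy (cluster order), making results independent
  of decoy input order on tie-free data.
* Receptor flexibility, solvation/H-bond terms, binding-site *prediction*,
  template detection and μ/σ derivation (restraints are an input file),
  and affinity scoring are out of scope.
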