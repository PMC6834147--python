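# Methods

This note records the models, algorithms, parameter choices, and known
limitations behind `ellipsomol`.

## Molecule model and input

A molecule is a flat, file-ordered list of atom spheres partitioned into
residues (key: chain id + residue number + insertion code). Coordinates are
kept in the PDB frame in ångström, without centering, so the camera
distances in the LOD predicate are in Å directly. PDB reading (via gemmi)
takes model 1 only, keeps alternate locations blank or "A" (the simplest
deterministic policy), always drops waters (HOH), and drops HETATM records
unless requested — the abstraction targets the polymer. Element symbols
come from the element columns, with a first-alphabetic-character fallback
for legacy files that lack them.

Van der Waals radii use the Bondi set (H 1.20, C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å) with a 1.50 Å default for anything else. Radii only shape
the bounding geometry, so the choice of table is not critical; it is
configurable.

## Synthetic molecules

`generate_synthetic_molecule(n_residues, atoms_per_residue, seed)` emulates
the geometry the clustering relies on: residues as spatially coherent blobs
strung along a smooth backbone-like curve. Residue centers follow a helix
(radius 8 Å, rise 3 Å and arc ≈ 6 Å per residue — protein-like scales);
atoms scatter around each center with σ = 1.1 Å (recentred so blobs stay
put), and radii are uniform in 1.2–1.8 Å, the realistic vdW range. All
draws come from one seeded generator, so molecules are bit-reproducible.

What it does **not** emulate: covalent geometry (bond lengths/angles),
secondary structure, side-chain packing, crystallographic artifacts, or
clashes between distant residues. Tests passing on these fixtures
demonstrate the algorithmic properties (restriction, counts, containment,
monotonicity) — not biological fidelity of any particular abstraction.

## Cluster hierarchy

Dissimilarity between two atom spheres is the **volume** of the smallest
sphere enclosing both (VDM); merging the pair that minimizes it keeps the
new cluster's bounding volume smallest. Cluster–cluster dissimilarity is
the unweighted mean of VDM over all leaf-atom pairs — "average" linkage —
maintained incrementally with the Lance–Williams UPGMA update
d(k, i∪j) = (nᵢ d(k,i) + nⱼ d(k,j)) / (nᵢ+nⱼ). The literature source for
the volume metric gives no formulas, so this pairing of "volume-based" with
UPGMA is the package's declared reading; the naive O(n³) re-computation of
the same definition is kept in the test suite as an oracle and reproduces
the optimized merge sequence exactly.

The residue restriction is enforced structurally, not heuristically: in
phase 1 only same-residue pairs are candidates; when the last residue
closes, an assertion verifies every live cluster is exactly one whole
residue before phase 2 opens all pairs. One n×n dissimilarity matrix
carries over between phases, so the phase-2 starting values are the true
leaf-pair averages.

Numerical choices:

- The pairwise matrix is built with radii summed before the center
  distance is added, making it bit-exactly symmetric; the exact-equality
  tie scan depends on this.
- Ties on dissimilarity break toward the lexicographically smallest
  (min node id, max node id) pair — trees are deterministic, and symmetric
  substructures merge in a reproducible order.
- A single-atom residue's leaf doubles as its residue cluster (flagged
  `residue_root`), preserving the 2n−1 node count.
- During clustering a cluster's sphere is the pairwise enclosing sphere of
  its children's spheres — cheap and monotone. The exact minimal enclosing
  sphere of the member atoms is recomputed per node afterwards for
  rendering and statistics.

Cost: the argmin scan is O(n²) per merge, O(n³) overall in the worst case;
a 1000-atom molecule builds in a few seconds, which is the intended desk
scale (the method's preprocessing is offline by design).

## Bounding volumes

**MVEE.** Khachiyan's barycentric ascent on the dual weights of the
lifted scatter matrix, stopped when the maximum lifted leverage is within
(1+ε)(d+1), then rescaled so the farthest point lies exactly on the
surface. Defaults: ε = 1e-3, ≤10⁴ iterations, k = 32 surface samples per
sphere/ellipsoid — a balance of accuracy against desk-scale runtime; none
of these is dictated by the method itself. Inputs that are affinely
rank-deficient raise a degenerate-input error; the tree annotator
regularizes by appending six ±1e-6 Å axis points and floors semi-axes at
1e-6 Å (unreachable for real atom samples, guarded anyway).

**Sampling.** Surfaces are sampled on a Fibonacci lattice (deterministic,
well spread, never coplanar for k ≥ 4); ellipsoid samples are the affine
image c + V diag(λ) u of unit-sphere samples. Residue-interior and residue
nodes fit their MVEE to the samples of **all member atoms**; residue-link
and molecule nodes fit theirs to the samples of their two children's
MVEEs — "previous level" is read as the node's children, the only
tree-local definition — which keeps high-level fits cheap and lets the
abstraction track the previous level rather than re-fitting raw atoms.

Consequences worth knowing: the MVEE encloses *sampled* surface points,
so exactness is bounded by k. In particular rotating a molecule changes
which sample points are extreme; tree-level MVEEs agree with the rotated
originals only to a few percent at k = 32 (the solver itself is
rotation-equivariant to solver tolerance, and is tested as such).

**Minimal enclosing sphere of spheres.** The convex program
min_c max_i (‖c−cᵢ‖ + rᵢ) solved in epigraph form with SLSQP from the
centroid start; the returned radius is re-tightened to the exact max-reach
at the solution, guaranteeing containment.

## LOD selection

The predicate D ≤ (dis − inival)/interval is evaluated with a real-valued
threshold (no flooring) against the integer subtree height D. Distance is
measured per cluster to its own center — MVEE center in ellipsoid mode,
minimal-sphere center in sphere mode — so a single frame mixes detail
bands across the molecule. Defaults inival = 100 Å, interval = 20 Å put a
~50 Å protein at full vdW detail at close range; both are plain config
values. `vdw` mode bypasses the predicate and always emits all atoms. The
traversal asserts the partition property (disjoint cover of all atoms) on
every call.

## Renderer

A CPU ray caster stands in for the GPU vertex/fragment pipeline: the
per-glyph *agent sphere* (concentric, radius = longest semi-axis) becomes
a conservative screen-space rectangle — projected corners of its
camera-space box, clamped to the full frame when the camera is beside or
inside the sphere — restricting which pixel rays are tested. Rays go
through pixel centers of a right-handed pinhole camera, origin top-left,
y down.

Ellipsoid intersection happens in glyph space: translate by −c, rotate by
Vᵀ, solve the canonical quadratic, rotate the normal (x/a², y/b², z/c²)
back. The rotation is rigid, so the ray parameter t needs no depth
correction; the depth buffer stores t in Å (∞ = background), which keeps
the silhouette threshold in physical units and makes brute-force oracles
trivial.

Post-processing defaults (all plain config, none dictated by the method):

- Diffuse shading: Lambert with ambient floor 0.2, headlight (light along
  the view direction) unless a light direction is given; constant mode
  returns the albedo (flat, Goodsell-style).
- Silhouettes: a pixel is marked when the max absolute depth difference to
  its 8 neighbours exceeds threshold × (1 + depth_scale × depth), defaults
  1.0 Å and 0.01/Å; foreground pixels adjacent to background are always
  marked. Marked pixels composite to black.
- SSAO: 16 cosine-weighted hemisphere offsets per pixel from a seeded
  golden-ratio low-discrepancy sequence, radius 3 Å, range check at twice
  the radius, 0.02 Å bias; occlusion darkens color as (1 − occlusion).
- Colors: per-level palette by default; `color_by = "residue"` gives each
  residue a stable hue.

PPM output is bit-exact by construction (P6, round-half-up on 255·value);
PNG goes through Pillow and is deterministic for identical buffers.

## Serialization and CLI

Trees are versioned JSON storing atoms, nodes, spheres, and ellipsoids as
center/axes/semi-axes (not the quadric matrix — no eigendecomposition
drift on reload); round-trips are exact to JSON float precision (≤1e-9).
The `ellipsomol` CLI exposes `build`, `select`, `render` (TOML config),
and `stats`; `stats` prints the sphere-vs-ellipsoid total-volume
comparison so the volume-reduction claim is a printed, testable number.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen as representative rather than
exhaustive: synthetic molecules up to 1000 atoms for tree structure, a
6×5-atom chain for annotation and LOD behavior, 64×64 frames for
brute-force depth comparison, and 512×512 for the end-to-end render.

## Known limitations

- Clustering is O(n³) worst case and single-threaded; rebuilding per
  conformation is the price of a precomputed hierarchy.
- MVEEs bound sampled points, not the exact union of balls; tightness and
  equivariance are k-limited (see above).
- No GPU path, no interactive rates, no frustum/occlusion culling, no
  smooth transitions between detail bands; mmCIF and multi-model NMR
  inputs are out of scope (model 1 only).
- The display-list monotonicity with camera distance holds for cameras
  beyond the molecule diameter (per-cluster distances can break it in the
  extreme near field, which the method accepts by design).
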