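# ellipsomol

Ellipsoidal level-of-detail (LOD) abstraction and illustrative rendering of
molecular surfaces.

Interactive visualization of large proteins (10⁵–10⁹ atoms) is limited by
the number of primitives drawn per frame. The classical remedy is LOD:
replace distant groups of atoms by a single coarser bounding shape. Bounding
**spheres** inflate badly as clusters grow — the abstracted molecule swells
and cavities close. This package implements the tighter alternative: a
complete binary cluster hierarchy over the atoms whose clusters are bounded
by **minimum-volume enclosing ellipsoids** (MVEEs), selected per frame by a
distance criterion, and drawn by implicit-surface glyph ray casting with
illustrative (Goodsell-style) shading. It is aimed at structural
bioinformatics and molecular-graphics work where the abstraction geometry
itself — not GPU frame rates — is the object of study.

## Method

**Residue-restricted clustering (AFHC).** Atoms are agglomerated under a
restrictive rule: atoms of the same residue must merge with each other
first; only when every residue has collapsed to a single cluster do
residues begin to merge. Dissimilarity uses a volume-based distance metric
(VDM): for two atom spheres it is the volume of the smallest sphere
enclosing both; between clusters it is the unweighted average over all
leaf-atom pairs (UPGMA, maintained by Lance–Williams updates). A molecule of
n atoms yields a complete binary tree of exactly 2n−1 nodes in five levels:
Atom, Residue-Interior, Residue, Residue-Link, Molecule.

**Ellipsoidal bounds.** Each internal node gets (a) the exact minimal
sphere enclosing its member atom spheres and (b) an MVEE, computed by
Khachiyan's (1+ε)-approximation. Residue-and-below MVEEs enclose surface
samples of all member atoms; higher MVEEs enclose surface samples of their
children's MVEEs, so the fit tracks the previous abstraction level.

**LOD selection.** For a camera at distance *dis* from a cluster C with
subtree height D, C is abstract enough when

    G(C, D) ≡ D ≤ (dis − inival) / interval

where *inival* is the distance at which simplification starts and
*interval* is the width of each detail band. A top-down traversal emits the
frontier of passing nodes (the *display list*); the emitted nodes always
partition the atom set.

**Rendering.** A software ray caster intersects each pixel ray with the
glyph quadric (x−c)ᵀA(x−c) = 1 in glyph space — A's eigenvectors are the
ellipsoid axes, its eigenvalues the reciprocal squared semi-axes — using a
concentric agent sphere of radius λmax to bound the tested pixels. Diffuse
or constant shading, depth-dependent silhouettes, and screen-space ambient
occlusion (SSAO) run as post-processing passes over the depth/normal
buffers.

## Worked example

```sh
ellipsomol build --synthetic 6,5,1 --out tree.json
ellipsomol stats --tree tree.json
```

builds the hierarchy for a synthetic 6-residue × 5-atom chain and prints:

```
atoms: 30
nodes: 59
  atom: 30
  residue_interior: 18
  residue: 6
  residue_link: 4
  molecule: 1
total internal-node sphere volume: 16516.683 A^3
total internal-node ellipsoid volume: 6678.004 A^3
ellipsoid/sphere volume ratio: 0.4043
```

59 nodes is the complete-binary-tree count 2·30−1; all five hierarchy
levels are populated; and the ellipsoidal bounds occupy only ~40% of the
volume of the corresponding minimal spheres — the inflation reduction that
motivates the ellipsoidal representation. To pick a display list and render
it:

```sh
ellipsomol select --tree tree.json --camera 0,0,160 --inival 100 --interval 15 --out dl.txt
ellipsomol render --tree tree.json --config render.toml --out frame.png
```

with `render.toml` such as

```toml
camera_position = [0.0, 0.0, 160.0]
camera_target = [4.0, 2.0, 8.0]
width = 512
height = 512
inival = 100.0
interval = 15.0
```

`select` writes one line per emitted node (id, glyph kind, center,
semi-axes, axis frame); with this pose it emits 8 glyphs mixing
residue-level ellipsoids with finer interior clusters and atoms, and
`render` ray-casts them into `frame.png` with silhouettes and SSAO.
Works on real structures too: `ellipsomol build --pdb 1ABC.pdb --out tree.json`.

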