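# Methods

## The model

`hydrosite` predicts where ordered (hydration) water molecules sit on a
protein's surface and in its cavities. The predictor is a binary 3D
convolutional classifier over local *trimming boxes*: cubic regions whose
protein heavy-atom distribution is voxelized into four binary channels,
one per element class (C, N, O, S). A box centred on a crystal-water
oxygen is a *water-present* pattern; a box centred on a point in the
hydration zone that carries no water is a *water-absent* pattern. The
classifier's sigmoid output is interpreted as the probability that the
box centre is a hydration site.

Two box resolutions are used. The fine box is 41 × 41 × 41 voxels of
0.25 Å (a 10.25 Å cube); the coarse box is 21 × 21 × 21 voxels of 0.50 Å.
Two classifiers with the same architecture are trained, one per
resolution. Prediction is a two-stage scan: the coarse model is evaluated
on a 0.50 Å lattice restricted to points within 4 Å of any
solvent-reachable protein atom (non-zero accessible surface area, ASA);
lattice points whose coarse probability reaches `coarse_threshold`
(default 0.1, mirroring the 10 % display contour) become candidates; the
fine model is then evaluated at every 0.25 Å voxel within `refine_radius`
(default 1.0 Å) of a candidate. The result is a probability map written
as MRC2014 (mode 2, x fastest axis, origin in the ORIGIN header words).
Predicted hydration sites are thresholded local maxima of the map
(default threshold 0.8) after non-maximum suppression within
`nms_radius`. The suppression default is 0.8 Å: it must exceed the
three-fine-voxel (0.75 Å) scale so duplicate discretization peaks
collapse, and it must stay safely below half the closest water–water
contact (2.4 Å / 2 = 1.2 Å) — at 1.2 Å the maxima of two adjacent
legitimate hydration sites suppress each other. A peak is only accepted
if its whole 26-neighbourhood was evaluated: voxels on the border of the
evaluated region compare against unevaluated zeros and would register as
spurious maxima.

## Architecture and training

The default network is the selected architecture of the study this
package operationalizes: a convolution block of two convolution units —
each unit being two 3 × 3 × 3 'same'-padded convolutions (ReLU),
2 × 2 × 2 max-pooling and dropout (rate 0.25) — followed by a fully
connected block with one 32-node hidden layer and a single sigmoid
output; all convolutions carry 32 channels. Spatial size is controlled
only by pooling (41 → 20 → 10 fine; 21 → 10 → 5 coarse; pooling floors a
trailing odd row). Training minimizes the clipped binary cross-entropy
(clip ε = 1e-7, natural log) with adaptive-moment (Adam) updates
(β₁ = 0.9, β₂ = 0.999, lr default 1e-3, batch 256). The accuracy /
precision / recall / F-measure decision rule is y ≥ 0.5 → present.

The network is implemented directly in numpy (forward, backprop, Adam) in
float32; training and inference are deterministic for a fixed seed on a
single CPU thread. Activations flow channels-last internally; the public
array contract is channels-first `(n, 4, e, e, e)`. Two numerical
specializations matter:

- the convolution is accumulated per filter tap as a GEMM over the
  channel axis, and its gradient was verified against float64 finite
  differences (max relative error ~5e-8);
- the first convolution layer detects sparse binary inputs (voxel
  patterns are overwhelmingly zero) and switches to a scatter/gather
  formulation that is orders of magnitude cheaper; it agrees with the
  dense path to float32 round-off and falls back to it for non-binary
  input.
- an independent triple-summation reference convolution
  (`conv3d_reference`) exists purely as a test oracle and is never used
  by the pipeline.

Max-pool gradients split equally among tied maxima (a valid max
subgradient; ties are common on all-zero windows). Dropout is inverted
and disabled at inference.

## Dataset construction

One water-present pattern is produced per crystal-water site, centred
exactly on the water oxygen; waters are never voxelized, so the pattern
encodes only the protein-atom distribution. Water-absent centres are
drawn (seeded, uniform, without replacement) from a candidate lattice of
0.25 Å pitch anchored at integer lattice multiples in the global frame,
restricted to the hydration zone: within 4.0 Å of a non-zero-ASA atom, at
least 2.0 Å from every protein heavy atom, and at least 2.4 Å from every
crystal-water oxygen (about the closest water–water contact). Balancing
is per structure — each structure contributes as many absent as present
patterns — so the surface-type mix stays representative; the dataset
total is exactly twice the corpus water count. The train/validation
split (default 70/30, floor rule) is per-pattern and deliberately ignores
structure boundaries; held-out whole structures are the guard against the
resulting leakage.

Voxelization is binary presence at the atom-centre voxel, axis-aligned in
the global frame with no rotation augmentation and no van-der-Waals
painting; two atoms in one voxel saturate at 1. Voxel intervals are
half-open (`index = floor((coord − corner)/voxel_size)`), so an atom
exactly on the box's upper face is excluded. A config switch for painted
spheres is deliberately not offered: binary single-voxel occupancy keeps
datasets bit-reproducible.

## Structure input and ASA

PDB parsing goes through gemmi: first MODEL only, ATOM records with
elements in {C, N, O, S} become channel atoms, residues named HOH/WAT
(oxygen only) become water sites, hydrogens, other elements and non-water
HETATM ligands are dropped. Alternate locations keep blank-or-'A' by
default (a `highest_occupancy` policy is available). Occupancy does not
weight voxel values.

ASA is Shrake–Rupley-style sphere-point sampling with a deterministic
golden-spiral point set (default 960 points), probe radius 1.4 Å, and a
fixed van-der-Waals table (C 1.70, N 1.55, O 1.52, S 1.80 Å). Waters do
not occlude. The tests cross-check per-atom values against an independent
implementation (biotite) and closed-form/Monte-Carlo oracles.

A site (or water) is classified *inside* (cavity/interface) versus
*first-layer* by computing its own ASA as a water-oxygen sphere against
protein atoms plus the other sites: zero ASA means isolated from bulk
solvent. Surface coverage counts first-layer predicted sites within the
4 Å shell at a nominal 20 Å² of surface per site, against the summed
per-atom ASA, capped at 100 %.

## Site matching

MAD is the mean absolute distance and RMSD the root-mean-square distance
between crystal-water sites and their matched predicted sites. Matching
is crystal → nearest predicted within a 3.0 Å default cutoff and is not
bijective (one predicted site may serve several crystal sites); unmatched
crystal sites are counted and excluded from N. The originating study does
not state its pairing rule, so its printed MAD/RMSD are not exactly
reproducible even with an identical model; reports therefore always state
the cutoff used.

## Synthetic data: what it emulates and what it does not

The generator packs `n_atoms` (default 60) heavy atoms with protein-like
composition (C 0.60, N 0.15, O 0.22, S 0.03) inside a 6 Å sphere by
seeded rejection sampling at ≥ 2.2 Å pairwise separation, then places one
"crystal water" per solvent-reachable N or O at 2.8 Å (a typical
hydrogen-bond length) along the outward direction from the cluster
centroid, skipping placements within 2.4 Å of anything. The outward
direction is centroid-based rather than a true surface normal — cheap,
deterministic, and sufficient to create a learnable polar-atom/geometry
signal analogous to hydrogen-bond-driven hydration.

What passing tests on this generator show: the full pipeline — ASA,
voxelization, balanced sampling, training, two-stage scanning, peak
extraction, matching — can learn and recover a deterministic local
hydration rule from patterns alone. What they do not show: performance on
real crystallographic hydration, which has tetrahedral hydrogen-bond
geometry, disorder, resolution- and contact-dependent missingness, and
far richer atom arrangements. The published headline numbers (accuracy
0.873 / loss 0.298 on 300 structures; MAD/RMSD 0.72/0.98 Å; 75 %
coverage) depend on a 2145-structure curated corpus and are out of desk
scale by construction.

## Scaled-down study conditions

The trainable checks (test fixtures and `scripts/acceptance.py`) run a
deliberately small instance of the same pipeline, chosen once as the
package's own problem size:

- corpus: 62 synthetic structures (~2,000 balanced patterns at 70/30);
  one extra structure held out entirely for end-to-end recovery;
- coarse box 13 voxels × 0.50 Å, fine box 23 voxels × 0.25 Å — both
  half-edges (3.25 / 2.875 Å) exceed the 2.8 Å hydration distance, so the
  parent-donor signal always lies inside the box;
- a narrow Model-6-shaped net: two convolution units (one 3³ convolution
  each at this scale) with 8 channels; a 16-node FCB for the coarse model
  (40 epochs, dropout 0.25) and a 32-node FCB with dropout 0.1 for the
  fine model (15 epochs, whose sparser 0.25 Å patterns need the extra
  fully-connected capacity); both lr 2e-3, batch 128. In a convergence
  comparison on the same corpus the two-conv-per-unit variant was
  slightly more accurate but several times slower; the one-conv variant
  already separates the rule comfortably, so it is used at this scale.
  Package defaults keep the full architecture.

Under these conditions the coarse classifier reaches held-out accuracy
≈ 0.93 and the end-to-end scan recovers well over 80 % of rule waters
within 1.0 Å (extraction threshold 0.5 for recovery; 0.8 remains the
default for calling sites on real maps).

## Degenerate inputs and tie-breaks

Empty trimming boxes are valid (all-zero grids classify without error).
Plateau maxima in site extraction resolve to the lexicographically
smallest voxel index; suppression order is descending probability with
lexicographic tie-break. Zero-match MAD/RMSD and zero-denominator
precision/recall report NaN with a warning rather than raising. MRC
stores no evaluation mask, so reading a map reconstructs the mask as the
nonzero voxels (an evaluated-but-exactly-zero voxel is indistinguishable
from an unevaluated one). The map reports zeros outside the refined
region rather than coarse probabilities.

## Known limitations

- Binary atom-centre voxelization discards sub-voxel geometry; the
  original images may have been encoded differently (the source is
  silent), making bit-level dataset equivalence with it impossible.
- No symmetry-mate expansion: waters coordinated by crystal contacts
  appear spuriously under-supported.
- Hydrophobic transmembrane belts would be predicted as hydratable; no
  masking is attempted.
- The per-pattern split leaks intra-structure information; all whole-
  structure claims in this package use fully held-out structures.
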