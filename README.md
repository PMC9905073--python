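# hydrosite

Prediction of the probability distribution of hydration water molecules
on protein surfaces and in cavities, from local voxelized atom
distributions, with a 3D convolutional neural network.

## The problem

High-resolution crystal structures resolve many — but never all — ordered
water molecules at the protein–water interface. Positional disorder,
limited resolution and crystal contacts leave the hydration structure of
the whole surface incomplete. `hydrosite` is for structural biologists
and simulators who need a complete hydration picture: it learns, from the
distribution patterns of protein C/N/O/S atoms around crystallographic
water sites, where water is likely to sit, and paints that probability
over the entire surface and interior cavities of a target structure.

## The model

A cubic *trimming box* around a point is voxelized into four binary
channels (carbon, nitrogen, oxygen, sulfur; one voxel set per atom
centre). A 3D CNN classifies the box centre as hydrated or not:

- convolution u_ijk = Σ_{p,q,r} x_{i+p, j+q, k+r} · f_pqr (3×3×3 filters,
  'same' padding, ReLU), organized as convolution units (conv layers +
  max-pool + dropout), then a fully connected block ending in a sigmoid
  output y ∈ [0, 1];
- training minimizes binary cross-entropy
  L(w) = −{d·log y + (1−d)·log(1−y)} with Adam, on a balanced set of
  water-present patterns (boxes centred on crystal waters) and
  water-absent patterns (points in the hydration zone with no water),
  split 70/30 per pattern;
- the default architecture is two convolution units of two 32-channel
  convolutions each and a 32-node fully connected layer.

Prediction runs coarse-to-fine: a coarse model (21³ voxels × 0.50 Å)
scans a 0.5 Å lattice within 4 Å of solvent-reachable atoms; a fine
model (41³ voxels × 0.25 Å) refines around candidates. Output is an
MRC2014 probability map plus hydration sites (thresholded local maxima,
default threshold 0.8); evaluation reports accuracy/precision/recall/
F-measure, MAD = (1/N)Σ|r_c − r_p| and RMSD = √(Σ(r_c − r_p)²/N) of
crystal-to-predicted site matches, and surface coverage at 20 Å² per
first-layer site.

Everything — including the CNN with its backprop and Adam — is numpy;
no deep-learning framework is required, and training is deterministic
per seed on one CPU thread.

## Worked example

Train on a synthetic corpus (the built-in generator places "crystal
waters" by a deterministic hydrogen-bond-like rule near exposed N/O
atoms) and predict a held-out structure:

```python
import numpy as np
import hydrosite as hs

corpus = hs.generate_corpus(62, hs.ToyStructureSpec(), seed=11)
heldout = hs.generate_structure(hs.ToyStructureSpec(seed=90001))

box = hs.BoxSpec(13, 0.50)                      # scaled-down coarse box
ds = hs.build_dataset(corpus, box, seed=11)     # balanced present/absent
split = hs.split_dataset(ds, 0.7, seed=11)
X, y = split.train.to_arrays()
Xv, yv = split.validation.to_arrays()

model = hs.HydrationCNN(channels=8, fcb_nodes=16, conv_layers_per_unit=1,
                        input_edge=13, epochs=40, batch_size=128,
                        learning_rate=2e-3, random_state=7,
                        box=box, resolution_tag="coarse").fit(X, y)
print(len(ds), "patterns; held-out accuracy",
      round(float(np.mean(model.predict(Xv) == yv)), 3))
```

which prints:

```
2066 patterns; held-out accuracy 0.934
```

2,066 balanced patterns were built from the corpus (one water-present
pattern per rule water plus an equal number of absent patterns), and the
classifier labels 93 % of held-out patterns correctly. The same model
pair then drives the scanner:

```python
pmap, sites = hs.predict_hydration(heldout, coarse_model, fine_model,
                                   site_threshold=0.5)
hs.write_mrc(pmap, "hydration.mrc")             # MRC2014 probability map
report = hs.mad_rmsd(heldout.water_coords, sites, match_cutoff=1.0)
print(f"recovered {report.N}/{heldout.n_waters} waters within 1 Å")
```

A CLI mirrors the library: `hydrosite inspect|simulate|build-dataset|
train|predict|evaluate` (see `hydrosite --help`).

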