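# Methods

## Problem and approach

`neoseg` addresses automatic configuration of an encoder-decoder dense CNN
for neonatal brain tissue segmentation (white matter, gray matter, CSF in
multimodal T1/T2-like MRI).  Rather than hand-tuning per-layer
hyperparameters, a team of 21 variable-structure learning automata searches
the discrete configuration space: one automaton per searchable convolution
layer (19 of them, each choosing among 375 `<filter count, length, width>`
triples) and one per searchable encoder pooling stage (2 of them, choosing
max vs average pooling).  The joint choice — 19 × 3 + 2 = 59 scalar
hyperparameters — fully specifies a candidate network.

Each search iteration every automaton draws an action, the candidate CNN is
built, trained, and scored by the mean Dice over the three tissue classes
on held-out volumes.  If the score strictly exceeds the best seen so far,
all automata reinforce their last actions and the configuration is saved;
otherwise all are penalised.  The search stops at the iteration cap `T`
(default 200), after `K` consecutive non-improving iterations (default 15),
or when the score reaches the ceiling `q_max` (default 1.0).

## Learning-automaton update scheme

Each automaton holds a probability vector `p` over its `K` actions,
initialised uniform (1/375 for convolution automata, {1/2, 1/2} for pooling
automata).  With chosen action `i`:

* reward (step `a`, default 0.5): `p_i ← p_i + a(1 − p_i)`,
  `p_j ← (1 − a) p_j` for `j ≠ i`;
* penalty (step `b`, default 0.5): `p_i ← (1 − b) p_i`,
  `p_j ← b/(K − 1) + (1 − b) p_j` for `j ≠ i`.

Both maps preserve `Σp = 1` algebraically; the vector is renormalised after
each update to absorb floating-point drift, keeping the invariant exact
over arbitrarily long runs.  The penalty's redistribution term is the
standard linear reward-penalty form `b/(K − 1)`: it is the unique uniform
redistribution that conserves probability mass.  Setting `b = 0` recovers
the linear reward-inaction scheme, which the tests also exercise.

Action selection is an exploration mixture: with probability 0.3 (the
`exploration_rate`) an action is drawn uniformly, otherwise from `p`.  The
exploration coin is flipped independently per automaton per iteration; a
per-automaton coin mixes the joint space faster than a single global coin
and is the weaker assumption.

No convergence guarantee is claimed for the reward-penalty scheme at
`a = b = 0.5`; the aggressive steps are kept configurable, and the search's
returned result is the best configuration *ever evaluated*, not the final
probability argmax, which makes the outer loop robust to non-convergent
automata dynamics.

## Network architecture

The skeleton is fixed; only per-layer hyperparameters are searched:

* three encoder dense blocks separated by the two searchable pooling
  stages (2× window, stride 2), then three decoder dense blocks with
  parameter-free nearest-neighbour 2× upsampling before the first two —
  total downsampling factor 4, and every convolution uses same-padding, so
  output extent always equals input extent;
* each dense block is three convolution → batch-norm → ReLU layers with
  dense connectivity by channel concatenation: layer `l` receives the block
  input plus all earlier layer outputs, so the third layer sees
  `C_in + N1 + N2` channels.  The block's output is its third layer's
  output, which bounds channel growth between blocks;
* a searchable final feature convolution (the 19th conv action) followed
  by a fixed 1×1(×1) projection to the class count and a per-voxel softmax.
  The projection is fixed because the output width is dictated by the
  number of classes, not by the 19th action's filter count;
* encoder and decoder blocks are configured independently (no symmetry
  constraint), and there are no skip connections between them.

Filter length × width are the two in-plane kernel extents.  For 3D inputs
the third extent is `min(length, 3)`, keeping volumetric kernels small; the
choice of the third extent is a genuinely open design point and this rule
is the package's convention.  The class count defaults to 4 (background +
CSF + GM + WM); Dice/ASD reporting covers the three tissue labels only.

The layers are implemented as a small CPU engine (`neoseg._engine`):
same-padded convolution evaluated as a loop over kernel offsets, each a
BLAS matrix product on the shifted input (bounded memory, no im2col
matrix), with hand-written backpropagation verified against central
finite differences layer by layer.  Arithmetic is float32.

## Candidate training

Loss is the sum of voxel-wise cross-entropy and a smoothed soft-Dice loss
(smoothing constant 1.0), pairing a well-conditioned gradient with the Dice
objective the search optimises.  The optimiser is Adam at learning rate
1e-3.  Training stops at `max_epochs` (default 200) or after
`patience_epochs` (default 15) epochs without improvement of the monitored
quantity — validation mean Dice when a validation set is supplied,
otherwise the negative training loss.  A non-finite loss marks the
candidate as diverged; the search maps that to quality 0 and continues.

Within one search every candidate is trained from the same seed, so the
quality signal reflects configuration differences rather than
initialisation luck.

## Segmentation metrics

* **Dice**: `2|S∩T| / (|S| + |T|)` on the binary masks of one label.
  When a label is absent from both volumes the masks are identical and the
  score is 1 by convention; this keeps perfect predictions perfect.
* **ASD**: boundary voxels are mask voxels with a face-adjacent neighbour
  outside the mask (4-neighbourhood in 2D, 6 in 3D; grid edges count as
  outside).  The metric is the mean nearest-boundary Euclidean distance
  from prediction surface to truth surface averaged symmetrically with the
  reverse direction, each direction normalised by its own point count.
  Distances use the physical voxel spacing in mm (default 1 mm isotropic),
  so ASD scales linearly with isotropic spacing.  An empty mask on either
  side is an error — a vanished prediction fails loudly rather than
  scoring 0.  Surface-to-surface (not region-to-region) distances are
  used, as is standard for a *surface* distance.  Nearest distances are
  computed with an exact Euclidean distance transform; tests verify
  equality with the brute-force all-pairs double loop to 1e-9.
* **mean quality**: the unweighted mean of per-label Dice over the tissue
  labels — the scalar the search maximises.

## Synthetic phantoms

The phantom generator emulates the statistical challenge of the real task
without any external data: nested tissue regions (background envelope, CSF
rim, GM ribbon, WM core) obtained by thresholding a radial coordinate
perturbed by a smoothed Gaussian random field (correlation length 4
voxels), over two co-registered modalities.  Default class mean
intensities order CSF < GM ≈ WM in modality 1 (T1-like) and WM ≈ GM < CSF
in modality 2 (T2-like), with a deliberately small GM/WM gap — the
low-contrast property that makes GM/WM separation the hard part.  Per-class
intensity jitter plus additive Gaussian noise (default σ 0.05 against a
unit intensity range, a mild noise level for structural MRI) complete the
image model, and each modality is standardised to mean 0, variance 1.
Generation retries with bounded internal sub-seeds until every tissue class
occupies ≥ 2% of voxels.

What the phantoms do **not** model: anatomical geometry, bias fields,
partial-volume mixtures beyond Gaussian jitter, or any acquisition
protocol.  Passing tests on phantoms therefore demonstrate that the search
machinery, training loop and metrics behave correctly and that the search
can exploit a learnable signal — not that the default configuration
reaches clinical-grade accuracy on real infant MRI.

Oracle reward tables (`make_oracle_table`) provide a second, fully
deterministic environment for testing the search loop without any neural
training: `additive` tables sum independent per-automaton utilities
(separable, easy), `single-peak` tables concentrate reward near one joint
action (harder).  Both record their known optimum and stay exhaustively
enumerable.

## Problem sizes used in the tests

The unit and property tests run on small masks (≤ 10³ voxels), 16×16 or
16³ phantoms, and 3–4-automaton oracle tables, chosen so the whole suite
runs in minutes on one CPU.  The end-to-end test drives the complete
pipeline — 21 automata, candidate CNN training, Dice-based environment,
JSONL logging — at 2D desk scale: eight 16×16 two-modality phantoms (six
training, two validation), a 5-iteration search with 2-epoch candidate
training, compared against five uniformly random genotypes trained
identically, paired over three seeds.  2D inputs are a first-class code
path (the model is rank-generic), and at this scale a full candidate
evaluation costs seconds rather than the hours a 3D 32³ candidate with
hundreds of channels would need, while exercising every line of the same
code.  The search defaults themselves (`T = 200`, `K = 15`,
`a = b = 0.5`, exploration 0.3, 32³ patches, batch 8) are unchanged and
are what `neoseg search` uses.

## Numerical choices and edge cases

* Probability vectors: renormalised and clipped to [0, 1] after every
  update; invariant asserted to 1e-9.
* Improvement test is strict (`quality > best`); ties are penalised.  The
  first iteration always improves on the initial best of −∞, so the first
  configuration is always rewarded and saved.
* All 21 automata share one global reward/penalty signal; there is no
  per-layer credit assignment.
* Environment exceptions during evaluation are logged as quality 0 and
  penalised; the search continues.
* Max-pool backward splits gradients evenly among tied maxima.
* Batch-norm uses batch statistics in training and running statistics
  (momentum 0.1) at inference.
* The search history is flushed to an append-only JSONL log after every
  iteration, so a crashed run is resumable from its log.

## Known limitations

* The CPU engine is adequate for desk-scale experiments only; 3D searches
  at realistic patch sizes need a GPU-backed implementation.
* Dense blocks return only their final layer's output; architectures that
  concatenate all block outputs would change channel accounting.
* No data augmentation, bias-field correction, or patch sampling beyond
  whole-volume batches is implemented.
* The reward-penalty scheme with `a = b = 0.5` is aggressive; for larger
  action spaces or noisier environments smaller steps (or `b = 0`) are
  advisable.
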