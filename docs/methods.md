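# Methods

## Graph construction

A triangular mesh (N vertices, M faces) defines an undirected binary
graph: for every face (i, j, k) the edges (i,j), (j,k), (i,k) are set,
duplicates across shared face edges collapse, and every node receives a
self-loop so aggregation retains its own features. Two distinct degree
conventions coexist deliberately:

* the **propagation operator** Â = D̃^(−1/2) Ã D̃^(−1/2) uses the
  self-looped degrees D̃ (the renormalization that confines the spectrum
  to [−1, 1]);
* the **normalized Laplacian** L = I − D^(−1/2) A D^(−1/2) uses the
  degrees of A without self-loops, as the spectral-filter theory it
  serves is stated that way.

Degree-0 vertices can occur only in corrupted meshes; the Laplacian then
substitutes the self-looped degree and emits a `RuntimeWarning` rather
than dividing by zero, since mesh defects are a known practical failure
mode of graph convolution on reconstructed cortices.

Edges are unweighted. Inverse-edge-length weighting was considered and
not adopted: the binary construction is the documented baseline and
keeps Â's spectrum analysis exact.

## Spectral oracles

`exact_spectral_filter` (U g(Λ) Uᵀ x via dense eigendecomposition,
restricted to n ≤ 2048) and `chebyshev_filter` (Σ θ′_k T_k(L̃) x with
L̃ = (2/λ_max) L − I and the standard recurrence T_k = 2xT_{k−1} − T_{k−2})
exist to *verify* the trained layer, not to power it: the model uses only
the K = 1 simplification with θ = θ′₀ = −θ′₁ after renormalization. The
default λ_max = 2 is the usual upper-bound approximation; the exact
λ_max is available for oracle comparisons, where polynomial filters of
degree ≤ 3 agree with the exact route to 1e−8 after basis conversion.

## Network

* **Layer order**: aggregate (Â H) → linear (W) → batch-norm → add
  residual → ReLU. With batch size fixed at one graph, batch-norm
  statistics are computed per channel over the N nodes (training mode)
  with running estimates (momentum 0.1) for inference; this is the only
  reading under which "batch" normalization is well defined here, and it
  makes the whole forward pass vertex-permutation equivariant.
* **Residuals**: identity when input and output widths match, a learned
  linear projection otherwise (widths change at every layer of the
  U-schedule, so projections are the norm).
* **U-shape and skips**: the architecture keeps full mesh resolution
  throughout — the "U" is the palindromic width schedule
  (16, 32, 64, 128, 64, 32, 16), not spatial pooling. With `long_skips`
  on (default), encoder output i is added to decoder output L−1−i for
  the width-matched mirror pairs ((0,6), (1,5), (2,4) in the 7-layer
  schedule; the bottleneck has no partner). Whether such skips are part
  of the original design is ambiguous, so they are a flag; both readings
  train.
* **SE block**: placed after the first convolution (position
  configurable for ablations), bottleneck ratio r = 4, no bias terms
  (per-channel shifts come from the batch-norm affines). Gates are
  strictly inside (0, 1), so SE can only attenuate channels.
* **Head**: a graph convolution (aggregating, like every other layer) to
  K channels followed by a row softmax. A non-aggregating per-vertex
  linear head would also be defensible; the aggregating form matches the
  two-layer closed form softmax(Â ReLU(Â X W⁰) W¹), which the degenerate
  configuration reproduces to 1e−6.
* **Dropout** (rate 0.1) is applied to node features before every
  layer's aggregation, including the head.
* **Initialization**: seeded Glorot-uniform for all weight matrices;
  batch-norm scale 1 / shift 0.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e−8) at learning rate 0.01 for 200 epochs, one
graph per optimizer step, subject order reshuffled per epoch with a
seeded generator. The loss is masked mean cross-entropy over labeled
vertices plus λ Σ‖W‖² over all weight matrices (batch-norm affines
excluded). λ is not part of the published protocol; the default 5e−4 is
standard practice for this family of models and nothing in the test
suite depends on its exact value. Features are standardized per subject
and channel (mean 0, sd 1 over the N vertices; constant channels map to
zero), consistent with per-graph batch normalization. Vertices carrying
the ignore sentinel (−1, e.g. annot entries whose color is absent from
the table) are excluded from loss, Dice and accuracy. No early stopping
or best-epoch selection: the epoch budget is fixed.

A NaN/Inf loss aborts training with a diagnostic rather than continuing
silently; with learning rate 0 the loop is a no-op on the parameters,
which the tests use as a contract check.

## Evaluation

Per-class Dice is micro-pooled: vertex counts |G_c|, |P_c|, |G_c ∩ P_c|
are summed across the test subjects before forming the ratio, then
macro-averaged over classes present in some ground truth. Classes absent
from both G and P are excluded (0/0); classes present in G but never
predicted score their computed Dice (possibly 0). Accuracy is
vertex-pooled across subjects (primary) with per-subject values also
recorded. Pooling conventions are a documented choice — per-subject
macro averaging is a reasonable alternative and reconstructable from the
recorded per-subject values.

## Synthetic benchmark

The generator emulates the *statistical shape* of the real inputs, not
their biophysics:

* **Mesh**: subdivided icosahedron projected to the unit sphere;
  midpoints deduplicated by exact index pairs, so |V| = 10·4^L + 2
  exactly (L = 5 gives the 10,242-vertex template resolution). Level 4
  (2,562 vertices) is the default cohort scale — large enough for an
  8-parcel topology with non-trivial boundaries, small enough that a
  full 200-epoch training finishes in minutes on one CPU.
* **Labels**: hop-distance (graph-geodesic) Voronoi cells around seed
  vertices, ties to the lowest seed index — deterministic, mesh-native,
  and each parcel is connected. Exact spherical-arc Voronoi would differ
  only at boundary ties.
* **Features**: 6 channels (matching the real channel count) of
  per-parcel Gaussian means (sd = `signal_strength`) plus vertex noise
  (sd = `noise_sd`) smoothed `smoothing_steps` times with the
  row-stochastic operator D̃^(−1) Ã. Smoothing (not Â, which would
  rescale rows unevenly) gives the noise the local spatial correlation
  real curvature/depth maps exhibit; on degree-regular graphs it also
  conserves the channel mean exactly.
* **Cohort variation**: a single scalar `subject_jitter` drives both a
  Poisson(`subject_jitter`)-many random-hop perturbation of each parcel
  seed and a N(0, (0.1·jitter)²) offset of the parcel means per subject.
  Defaults (jitter 1) displace most parcel boundaries by about one
  vertex ring between subjects.
* **Default conditions** (level 4, 8 parcels, signal 3, noise 1,
  smoothing 2, jitter 1, 10 subjects) define the benchmark on which the
  full model is expected to reach held-out mean Dice ≥ 0.90. The
  `vertex_area` operator (one third of incident triangle areas, summing
  exactly to the mesh area and converging to 4π on the unit icosphere)
  documents how one real channel is computed, but the benchmark channels
  are purely statistical.

**What passing does and does not show**: synthetic parcels are
feature-separable by construction (Mahalanobis distance between random
parcel-mean pairs ≈ signal_strength·√12 across 6 channels), so
near-perfect synthetic Dice demonstrates that graph construction,
propagation, attention, training and evaluation are wired correctly — it
says nothing about accuracy on real cortices, where class boundaries are
not feature-homogeneous and 31 regions with strong size imbalance make
the problem far harder.

## Numerical choices

* All computation in float64; gradients from the in-repo reverse-mode
  autodiff core agree with central finite differences to 1e−4 relative
  on small graphs.
* Probabilities are clamped at 1e−12 inside the cross-entropy only.
* Softmax rows sum to 1 within 1e−6 (asserted); `predict_labels` rejects
  matrices violating this and breaks argmax ties toward the lowest
  class index.
* Sparse operators are CSR with sorted indices; dense materialization is
  confined to oracles (n ≤ ~2,000).
* Determinism: every stochastic component (init, shuffling, dropout,
  generator) is driven by explicit seeds; two runs with equal seeds are
  bit-identical in single-threaded mode.

## Known limitations

* The real-data path is exercised end-to-end only on synthetic cohorts
  exported to FreeSurfer formats; no imaging data ships with the
  package.
* One graph per step means no gradient averaging across subjects;
  convergence on very heterogeneous cohorts may need more epochs.
* The quad surface dialect and GIFTI/CIFTI are unsupported by design.
* Training at the full 10,242-vertex resolution with 100 subjects is
  CPU-feasible but slow (hours); the implementation targets method study
  and desk-scale benchmarks, not production throughput.
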