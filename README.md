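# adgcn

Attention-guided deep graph convolutional parcellation of cortical
surface meshes, **directly in the native mesh domain** — no spherical
inflation, mapping or registration step.

## The problem

Cortical surface parcellation assigns an anatomical region label (e.g.
one of the 31 regions of the DKT protocol) to every vertex of a
reconstructed white-matter surface mesh. Classic pipelines first inflate
the highly folded cortex to a sphere and register it to an atlas, which
is slow (hours per hemisphere) and distorts the geometry. Because the
mesh is a graph, a graph neural network can instead label the vertices
where they live.

This package is for researchers who have per-vertex morphology
(FreeSurfer `curv`-format channels: area, mean curvature, Jacobian
distortion, sulcal depth, thickness, volume) on surfaces resampled to a
common icosphere resolution (fsaverage5, 10,242 vertices per
hemisphere), and want an end-to-end trainable vertex classifier — or a
fully synthetic benchmark to study one.

## The model

Each subject's mesh becomes an undirected binary graph with self-loops:
Ã = A + I_N, D̃ᵢᵢ = Σⱼ Ãᵢⱼ. Layers propagate features with the
renormalized first-order graph convolution

    H^(l+1) = σ( BN( Â H^(l) W^(l) ) + R(H^(l)) ),   Â = D̃^(-1/2) Ã D̃^(-1/2)

whose spectrum lies in [−1, 1] (the unnormalized I + D^(−1/2) A D^(−1/2)
reaches eigenvalue 2, destabilizing deep stacks; both facts are verified
numerically in the test suite, and exact spectral / Chebyshev filters are
kept as oracles for the first-order form). R is a per-layer residual
connection (identity, or a learned projection when the width changes).

The hidden widths follow a palindromic U-shaped schedule
(16, 32, 64, 128, 64, 32, 16) with additive long skip connections between
width-matched mirror layers. After the first layer a graph
squeeze-and-excitation block recalibrates channels: a global average pool
z_c = (1/N) Σᵢ h_c(i), a bottleneck s = σ(W₂ ReLU(W₁ z)) with reduction
ratio r = 4, and channel-wise rescaling h̃_c = s_c · h_c. A final graph
convolution to K classes with a row softmax yields per-vertex
probabilities; training uses cross-entropy + L2 with Adam (lr 0.01,
dropout 0.1, 200 epochs, one graph per step) under subject-level 5-fold
cross-validation. Performance is reported as per-region Dice
2|G∩P|/(|G|+|P|) and overall vertex accuracy |G∩P|/|G|.

The network and its training loop are implemented on a small in-repo
reverse-mode autodiff core over numpy (`adgcn.autodiff`) — no deep
learning framework required.

## Worked example

```python
import numpy as np
from adgcn import (SyntheticSpec, make_dataset, ModelConfig, TrainConfig,
                   train, evaluate, preset)
from adgcn.train import kfold_split

spec = SyntheticSpec(level=3, n_parcels=6, signal_strength=3.0, noise_sd=1.0,
                     smoothing_steps=2, subject_jitter=1.0, seed=42)
cohort = make_dataset(10, spec)          # ten 642-vertex subjects
by_id = {s.id: s for s in cohort}
train_ids, test_ids = kfold_split([s.id for s in cohort], folds=5, seed=42)[0]

config = ModelConfig(**{**preset("adgcn").__dict__, "n_classes": 6})
params, history = train([by_id[i] for i in train_ids], config,
                        TrainConfig(epochs=100, seed=42))
report = evaluate(params, [by_id[i] for i in test_ids])
print(f"training loss: {history[0]:.3f} -> {history[-1]:.3f}")
print(f"held-out mean Dice: {report.mean_dice:.4f}")
print(f"held-out accuracy:  {report.accuracy:.4f}")
```

prints

```
training loss: 1.459 -> 0.059
held-out mean Dice: 0.9934
held-out accuracy:  0.9945
```

i.e. on a 10-subject synthetic cohort (6 Voronoi parcels per 642-vertex
icosphere, parcel-mean separation 3 noise-sd units, spatially smoothed
noise, jittered parcel boundaries across subjects) the full 7-layer + SE
model labels held-out subjects almost perfectly — the loss falls from
near ln 6 ≈ 1.79 (chance) to 0.06, and both metrics exceed 0.99.

The same workflow is available from the shell, reading and writing
FreeSurfer binary formats throughout:

```sh
adgcn simulate --out data --seed 5 --n-subjects 10
adgcn train    --data data --out run --seed 5
adgcn predict  --model run/model-full.npz --subject data/sub-000 \
               --out preds/sub-000.annot
adgcn evaluate --pred preds --truth data
```

## Scope

Surface reconstruction, spherical resampling to fsaverage5, and the
computation of the real morphological features are upstream (FreeSurfer)
concerns: this package consumes their outputs (`surface`, `curv`,
`annot` files) or synthesizes statistical stand-ins. See
`docs/methods.md` for modelling details, parameter choices and
limitations.
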