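# cellbridge

Online integration of multi-batch single-cell data (scRNA-seq, scATAC-seq,
and cross-modality gene-activity matrices) with a variational autoencoder
whose encoder is batch-free and whose decoder carries all batch-specific
structure.

## The problem and the model

Single-cell datasets collected across donors, platforms, or protocols carry
systematic non-biological differences (batch effects). Most correction
methods search for cell correspondences between batches, which mixes
populations that exist in only some batches ("over-correction") and requires
re-running the whole integration whenever data arrives. `cellbridge` instead
learns a *global* projection: a VAE encoder

    x  →  fc(1024) — BN — ReLU — fc(10) × 2  →  μ, log σ²,   z = μ + σ ⊙ ε

that never sees batch labels, paired with a one-layer decoder

    z, b  →  fc — DSBN(b) — sigmoid  →  x̂

where DSBN (domain-specific batch normalization) keeps one set of
normalization parameters per batch b. The loss is

    BCE(x̂, x) + 0.5 · D_KL( N(μ, σ²) ‖ N(0, I) ),

optimized with Adam (lr 2e-4, weight decay 5e-4) on mini-batches of 64 drawn
from all batches pooled. Because batch identity enters only in the decoder,
the encoder learns batch-invariant biology and generalizes: a **new batch is
integrated by a single frozen-encoder pass** — no retraining, no change to
existing embeddings — and annotated by k-NN label transfer in the latent
space. The network and its exact gradients are implemented directly in
numpy; no deep-learning framework is required.

The package bundles the full preprocessing recipes, a synthetic multi-batch
generator with known ground truth (including partial-overlap designs), and
the complete metric suite: ARI, NMI, silhouette, batch entropy mixing,
iLISI/cLISI, over-correction score, macro F1, similarity and confusion
matrices. See `docs/methods.md` for definitions and conventions.

## Worked example

```python
import cellbridge as cb

raw = cb.preset_integration(seed=0)          # 900 cells, 3 batches, 4 types
result = cb.integrate(raw, max_iterations=5000, seed=0)
print(f"ARI {result.report.ari:.3f}  "
      f"mixing {result.report.batch_entropy_mixing:.3f}  "
      f"over-correction {result.report.over_correction:.3f}")

hold = cb.holdout_projection(raw, holdout_batch="batch2", seed=0)
print(f"label-transfer accuracy on the projected batch: {hold.accuracy:.3f}")
```

Output:

```
ARI 0.997  mixing 0.975  over-correction 0.002
label-transfer accuracy on the projected batch: 1.000
```

Read: Leiden clusters of the integrated latent space agree with the true
cell types (ARI 0.997, where the uncorrected PCA baseline reaches only
0.426); batches are almost perfectly interleaved (mixing 0.975 of 1);
essentially no latent neighbors cross type boundaries (no over-correction);
and a batch the model never saw is annotated perfectly after a pure encoder
pass. The `examples/` directory has one narrative script per
capability: integration, online projection, partial overlap, ablations, and
ATAC preprocessing.

The same workflow is available from the shell:

```bash
cellbridge simulate --seed 0 -o sim.h5ad
cellbridge preprocess -i sim.h5ad --min-genes 10 --n-top 300 -o scaled.h5ad
cellbridge train -i scaled.h5ad --seed 0 -o model.cbz
cellbridge project -m model.cbz -i new_batch.h5ad -o projected.h5ad
cellbridge annotate -r reference.h5ad -q projected.h5ad -k 30 -o labels.tsv
cellbridge evaluate -i projected.h5ad --seed 0 -o report.json
```

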