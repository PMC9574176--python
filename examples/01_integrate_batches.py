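"""Integrate three synthetic batches sharing four cell types.

Simulates multi-batch scRNA-seq counts with a strong batch effect, runs the
preprocessing recipe and trains the VAE, then clusters the 10-D latent space
and scores the result. A good integration shows a high ARI (latent clusters
match the true cell types), a batch-entropy mixing score near 1 (batches are
interleaved), and a low over-correction score (distinct types not mixed).
"""

import warnings

warnings.filterwarnings("ignore")

import cellbridge as cb

raw = cb.preset_integration(seed=0)
print(f"simulated {raw.n_obs} cells x {raw.n_vars} genes, "
      f"{raw.obs['batch'].nunique()} batches, "
      f"{raw.obs['cell_type'].nunique()} cell types")

result = cb.integrate(raw, max_iterations=5000, seed=0)
print(f"training stopped after {result.log.iterations} iterations "
      f"({result.log.stop_reason}), best epoch {result.log.best_epoch}")

r = result.report
print(f"ARI (latent Leiden vs true types):   {r.ari:.3f}")
print(f"NMI:                                 {r.nmi:.3f}")
print(f"batch entropy mixing (0-1, high=mixed): {r.batch_entropy_mixing:.3f}")
print(f"over-correction (0-1, low=good):     {r.over_correction:.3f}")

baseline = cb.raw_baseline_embedding(raw)
baseline_ari = cb.adjusted_rand_index(
    baseline.cell_type_labels, cb.cluster_latent(baseline, seed=0)
)
print(f"uncorrected PCA baseline ARI:        {baseline_ari:.3f}")
print("the integrated embedding recovers cell types that the batch effect "
      "hides in the raw data")
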