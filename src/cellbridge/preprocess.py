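"""Preprocessing of raw multi-batch count matrices into model input.

Raw counts are filtered, library-size normalized, log-transformed, restricted
to the most variable features and finally max-abs scaled to [0, 1] *within
each batch*. The per-(batch, feature) maxima are kept in the output so that
a trained model's input convention can be reproduced at projection time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData

BATCH_KEY = "batch"
SCALING_KEY = "scaling_record"
PROVENANCE_KEY = "preprocess_params"


@dataclass
class PreprocessParams:
    """Filtering / normalization / feature-selection settings.

    Defaults follow the standard recipe: cells expressing fewer than 600
    genes and genes seen in fewer than 3 cells are dropped, totals are
    normalized to 10,000 (RNA) or the median total (ATAC), and the top 2,000
    variable genes (RNA) or 30,000 variable peaks/bins (ATAC) are kept.
    """

    min_genes_per_cell: int = 600
    min_cells_per_gene: int = 3
    target_sum: float | str = 10_000
    n_top_features: int = 2_000
    modality: str = "rna"

    def __post_init__(self):
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.n_top_features < 1:
            raise ValueError("n_top_features must be >= 1")

    @classmethod
    def atac_defaults(cls, **overrides) -> "PreprocessParams":
        kw = dict(
            min_genes_per_cell=0,
            min_cells_per_gene=3,
            target_sum="median",
            n_top_features=30_000,
            modality="atac",
        )
        kw.update(overrides)
        return cls(**kw)


def _validate_counts(adata: AnnData, batch_key: str) -> None:
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    if batch_key not in adata.obs:
        raise ValueError(f"missing batch label column {batch_key!r}")
    X = adata.X
    mn = X.min() if not sp.issparse(X) else X.data.min() if X.nnz else 0
    if mn < 0:
        raise ValueError("count matrix contains negative values")


def _as_dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def maxabs_scale_per_batch(adata: AnnData, batch_key: str = BATCH_KEY) -> pd.DataFrame:
    """Scale each feature to [0, 1] within each batch, in place.

    Returns the per-(batch, feature) maximum absolute values used (rows:
    batches, columns: features). Features with no signal in a batch keep a
    recorded maximum of 1 so the transform is the identity there.
    """
    X = _as_dense(adata.X).astype(np.float64)
    batches = adata.obs[batch_key].astype(str).values
    record = pd.DataFrame(
        1.0, index=pd.unique(batches), columns=adata.var_names, dtype=float
    )
    for b in record.index:
        rows = batches == b
        mx = np.abs(X[rows]).max(axis=0)
        mx_safe = np.where(mx > 0, mx, 1.0)
        X[rows] = X[rows] / mx_safe
        record.loc[b] = mx_safe
    adata.X = X
    return record


def _select_variable_rna(adata: AnnData, n_top: int, batch_key: str) -> AnnData:
    """Batch-aware dispersion-based highly variable gene selection.

    Genes are ranked by the number of batches in which they are highly
    variable, ties broken by mean normalized dispersion (the multi-batch
    behaviour of the standard dispersion flavor).
    """
    n_top = min(n_top, adata.n_vars)
    if n_top >= adata.n_vars:
        return adata
    n_batches = adata.obs[batch_key].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata,
            n_top_genes=n_top,
            flavor="seurat",
            batch_key=batch_key if n_batches > 1 else None,
        )
    return adata[:, adata.var["highly_variable"].values].copy()


def _finalize(adata: AnnData, params: PreprocessParams, batch_key: str) -> AnnData:
    record = maxabs_scale_per_batch(adata, batch_key)
    adata.uns[SCALING_KEY] = record
    adata.uns[PROVENANCE_KEY] = asdict(params)
    return adata


def preprocess_rna(
    raw: AnnData, params: PreprocessParams | None = None, batch_key: str = BATCH_KEY
) -> AnnData:
    """Full scRNA-seq recipe: filter, total-normalize, log1p, select variable
    genes, per-batch max-abs scale to [0, 1]."""
    params = params or PreprocessParams()
    if params.modality != "rna":
        raise ValueError("preprocess_rna requires modality='rna'")
    _validate_counts(raw, batch_key)
    adata = raw.copy()
    sc.pp.filter_cells(adata, min_genes=params.min_genes_per_cell)
    sc.pp.filter_genes(adata, min_cells=params.min_cells_per_gene)
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("all cells/genes filtered out; relax the thresholds")
    target = None if params.target_sum == "median" else float(params.target_sum)
    sc.pp.normalize_total(adata, target_sum=target)
    sc.pp.log1p(adata)
    adata = _select_variable_rna(adata, params.n_top_features, batch_key)
    return _finalize(adata, params, batch_key)


def preprocess_atac(
    raw: AnnData, params: PreprocessParams | None = None, batch_key: str = BATCH_KEY
) -> AnnData:
    """scATAC-seq recipe: binarize, filter sparse bins, keep the most variable
    bins, normalize totals to the median, per-batch max-abs scale."""
    params = params or PreprocessParams.atac_defaults()
    if params.modality != "atac":
        raise ValueError("preprocess_atac requires modality='atac'")
    _validate_counts(raw, batch_key)
    adata = raw.copy()
    adata.X = (_as_dense(adata.X) > 0).astype(np.float64)
    sc.pp.filter_genes(adata, min_cells=params.min_cells_per_gene)
    if params.min_genes_per_cell > 0:
        sc.pp.filter_cells(adata, min_genes=params.min_genes_per_cell)
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("all cells/bins filtered out; relax the thresholds")
    n_top = min(params.n_top_features, adata.n_vars)
    if n_top < adata.n_vars:
        # variability statistic: variance of the binarized matrix, p(1-p).
        # Ranked via the integer k(n-k) so exact ties resolve deterministically
        # by column order rather than by float round-off.
        k = _as_dense(adata.X).sum(axis=0).astype(np.int64)
        score = k * (adata.n_obs - k)
        keep = np.sort(np.argsort(-score, kind="stable")[:n_top])
        adata = adata[:, keep].copy()
    sc.pp.normalize_total(adata, target_sum=None)  # median of totals
    return _finalize(adata, params, batch_key)


def align_projection_features(
    new: AnnData,
    reference_features: pd.Index | list[str],
    params: PreprocessParams | None = None,
    batch_key: str = BATCH_KEY,
) -> AnnData:
    """Prepare a new batch for projection through a trained encoder.

    The new data is normalized per its modality recipe, restricted and
    re-ordered to the trained model's feature vocabulary (zero-filling
    features the new data lacks) and max-abs scaled within the *new* batch
    only. The model's encoder then sees input of exactly the width and
    convention it was trained on; no feature re-selection happens here.
    """
    params = params or PreprocessParams()
    _validate_counts(new, batch_key)
    reference_features = pd.Index(reference_features)
    overlap = new.var_names.intersection(reference_features)
    if len(overlap) == 0:
        raise ValueError(
            "no overlap between new data features and the model vocabulary "
            f"(0 of {len(reference_features)} reference features present)"
        )
    adata = new.copy()
    if params.modality == "atac":
        adata.X = (_as_dense(adata.X) > 0).astype(np.float64)
        sc.pp.normalize_total(adata, target_sum=None)
    else:
        target = None if params.target_sum == "median" else float(params.target_sum)
        sc.pp.normalize_total(adata, target_sum=target)
        sc.pp.log1p(adata)

    X = _as_dense(adata.X)
    out = np.zeros((adata.n_obs, len(reference_features)))
    col_of = {g: j for j, g in enumerate(reference_features)}
    src = [j for j, g in enumerate(adata.var_names) if g in col_of]
    dst = [col_of[adata.var_names[j]] for j in src]
    out[:, dst] = X[:, src]

    aligned = AnnData(
        X=out,
        obs=adata.obs.copy(),
        var=pd.DataFrame(index=reference_features),
    )
    return _finalize(aligned, params, batch_key)
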