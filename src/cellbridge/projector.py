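"""Online projection, label transfer, and latent-space analysis.

A trained encoder is a fixed function from scaled expression profiles to the
shared latent space. Projecting a new batch is therefore a read-only, eval-
mode encoder pass — no retraining, no registration of the new batch in the
decoder, and no change to previously integrated cells. Cell-type annotation
then transfers labels from reference cells to query cells that land at the
same latent locations (k-nearest-neighbor majority vote).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from .network import IntegrationVAE
from .preprocess import BATCH_KEY


@dataclass
class LatentEmbedding:
    """Cell x latent_dim posterior means with their cell annotations."""

    coords: np.ndarray
    cell_ids: list[str]
    batch_labels: np.ndarray
    cell_type_labels: np.ndarray | None = None
    source: str = "reference"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("latent coordinates must be finite")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length must equal the row count")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def to_anndata(self) -> AnnData:
        obs = pd.DataFrame(index=self.cell_ids)
        obs["batch"] = np.asarray(self.batch_labels).astype(str)
        if self.cell_type_labels is not None:
            obs["cell_type"] = np.asarray(self.cell_type_labels).astype(str)
        obs["source"] = self.source
        ad = AnnData(X=self.coords.copy(), obs=obs)
        ad.obsm["X_latent"] = self.coords.copy()
        return ad


@dataclass
class LabelTransferResult:
    predicted_labels: np.ndarray
    confidence: np.ndarray  # majority vote fraction, in (0, 1]
    k: int


def concat_embeddings(a: LatentEmbedding, b: LatentEmbedding) -> LatentEmbedding:
    types = None
    if a.cell_type_labels is not None and b.cell_type_labels is not None:
        types = np.concatenate([a.cell_type_labels, b.cell_type_labels])
    return LatentEmbedding(
        coords=np.vstack([a.coords, b.coords]),
        cell_ids=list(a.cell_ids) + list(b.cell_ids),
        batch_labels=np.concatenate([a.batch_labels, b.batch_labels]),
        cell_type_labels=types,
        source="mixed",
    )


def project(
    model: IntegrationVAE,
    new_scaled: AnnData,
    batch_key: str = BATCH_KEY,
    source: str = "projected",
) -> LatentEmbedding:
    """Encode preprocessed cells into the latent space with the frozen encoder.

    The feature vocabulary of ``new_scaled`` must equal the model's (use
    :func:`~cellbridge.preprocess.align_projection_features` first). Returns
    posterior means; the model is never modified.
    """
    vocab = getattr(model, "_feature_names", None)
    if vocab is not None:
        new_vocab = list(new_scaled.var_names)
        if new_vocab != list(vocab):
            missing = len(set(vocab) - set(new_vocab))
            extra = len(set(new_vocab) - set(vocab))
            raise ValueError(
                "feature vocabulary mismatch with the trained model: "
                f"{missing} model features missing, {extra} unknown features, "
                "or wrong column order; run align_projection_features first"
            )
    X = np.asarray(
        new_scaled.X.todense() if hasattr(new_scaled.X, "todense") else new_scaled.X,
        dtype=np.float64,
    )
    domains = None
    if model.config.variant == "encoder_with_batch":
        names = getattr(model, "_domain_names", None)
        labels = new_scaled.obs[batch_key].astype(str).values
        if names is None or not set(labels) <= set(names):
            raise ValueError(
                "encoder_with_batch models can only encode batches seen in "
                "training; online projection of new batches is not possible "
                "with this ablation"
            )
        lut = {b: i for i, b in enumerate(names)}
        domains = np.array([lut[b] for b in labels])
    mu, _ = model.encode(X, train=False, domains=domains)
    types = None
    if "cell_type" in new_scaled.obs:
        types = new_scaled.obs["cell_type"].astype(str).values
    return LatentEmbedding(
        coords=mu,
        cell_ids=list(new_scaled.obs_names),
        batch_labels=new_scaled.obs[batch_key].astype(str).values,
        cell_type_labels=types,
        source=source,
    )


def transfer_labels(
    reference: LatentEmbedding,
    query: LatentEmbedding,
    k: int = 30,
    exclude_self: bool = False,
) -> LabelTransferResult:
    """Majority-vote label transfer over the k nearest reference cells.

    Euclidean distances in latent space. Ties are broken by the smaller sum
    of distances to the voting neighbors, then lexicographically. With
    ``exclude_self=True`` (for query == reference), each cell's zero-distance
    self-match is dropped from its neighbor list.
    """
    if reference.cell_type_labels is None:
        raise ValueError("reference embedding has no cell_type labels")
    if k < 1 or k > reference.n_cells - int(exclude_self):
        raise ValueError(f"k={k} out of range for {reference.n_cells} reference cells")
    n_query = query.n_cells
    nn = NearestNeighbors(n_neighbors=k + int(exclude_self)).fit(reference.coords)
    dist, idx = nn.kneighbors(query.coords)
    if exclude_self:
        dist, idx = dist[:, 1:], idx[:, 1:]
    ref_labels = np.asarray(reference.cell_type_labels).astype(str)
    predicted = np.empty(n_query, dtype=object)
    confidence = np.empty(n_query)
    for i in range(n_query):
        votes = ref_labels[idx[i]]
        labels, counts = np.unique(votes, return_counts=True)
        top = counts.max()
        tied = labels[counts == top]
        if len(tied) > 1:
            dist_sum = {lab: dist[i][votes == lab].sum() for lab in tied}
            best = min(dist_sum.values())
            tied = sorted(lab for lab, s in dist_sum.items() if s == best)
        predicted[i] = tied[0]
        confidence[i] = top / k
    return LabelTransferResult(
        predicted_labels=predicted.astype(str), confidence=confidence, k=k
    )


def similarity_matrix(
    emb: LatentEmbedding,
    batch_pair: tuple[str, str],
) -> pd.DataFrame:
    """Pearson correlation between per-type latent centroids of two batches.

    ``S.loc[i, j]`` correlates the centroid of cell type ``i`` in the first
    batch with that of cell type ``j`` in the second. Types with no cells in
    a batch are omitted from that axis.
    """
    if emb.cell_type_labels is None:
        raise ValueError("embedding has no cell_type labels")
    batches = np.asarray(emb.batch_labels).astype(str)
    types = np.asarray(emb.cell_type_labels).astype(str)

    def centroids(batch: str) -> dict[str, np.ndarray]:
        rows = batches == batch
        if not rows.any():
            raise ValueError(f"batch {batch!r} has no cells")
        out = {}
        for t in sorted(set(types[rows])):
            out[t] = emb.coords[rows & (types == t)].mean(axis=0)
        dropped = set(types) - set(out)
        if dropped:
            warnings.warn(f"types absent from batch {batch!r}: {sorted(dropped)}")
        return out

    cen1, cen2 = centroids(batch_pair[0]), centroids(batch_pair[1])
    S = pd.DataFrame(index=sorted(cen1), columns=sorted(cen2), dtype=float)
    for i in S.index:
        for j in S.columns:
            S.loc[i, j] = float(np.corrcoef(cen1[i], cen2[j])[0, 1])
    return S


def confusion_matrix(true_labels, predicted_labels) -> pd.DataFrame:
    """Row-percent confusion matrix: entry (i, j) is the percentage of cells
    known to be type i that were predicted type j. Rows sum to 100."""
    true_labels = np.asarray(true_labels).astype(str)
    predicted_labels = np.asarray(predicted_labels).astype(str)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must be aligned per cell")
    rows = sorted(set(true_labels))
    cols = sorted(set(predicted_labels))
    C = pd.DataFrame(0.0, index=rows, columns=cols)
    for t in rows:
        mask = true_labels == t
        labs, counts = np.unique(predicted_labels[mask], return_counts=True)
        C.loc[t, labs] = 100.0 * counts / mask.sum()
    return C


def _neighbors(adata: AnnData, n_neighbors: int, seed: int) -> int:
    k = min(n_neighbors, adata.n_obs - 1)
    if k < n_neighbors:
        warnings.warn(f"n_neighbors reduced to {k} for {adata.n_obs} cells")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_latent", random_state=seed)
    return k


def cluster_latent(
    emb: LatentEmbedding,
    resolution: float = 0.5,
    n_neighbors: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Leiden communities on the Euclidean kNN graph of the latent coords."""
    if emb.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    if np.allclose(emb.coords, emb.coords[0]):
        warnings.warn("all latent coordinates identical; returning one cluster")
        return np.zeros(emb.n_cells, dtype=int)
    ad = emb.to_anndata()
    _neighbors(ad, n_neighbors, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.leiden(
            ad, resolution=resolution, random_state=seed, flavor="leidenalg"
        )
    return ad.obs["leiden"].astype(int).values


def umap_embed(
    emb: LatentEmbedding,
    n_neighbors: int = 30,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Seeded 2-D UMAP of the latent coordinates (Euclidean 30-NN graph)."""
    if emb.n_cells < 3:
        raise ValueError("need at least 3 cells for a UMAP embedding")
    ad = emb.to_anndata()
    _neighbors(ad, n_neighbors, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.umap(ad, min_dist=min_dist, random_state=seed)
    coords = np.asarray(ad.obsm["X_umap"], dtype=np.float64)
    if not np.isfinite(coords).all():
        raise FloatingPointError("UMAP produced non-finite coordinates")
    return coords
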