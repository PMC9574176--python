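"""Integration-quality metrics.

Two families: cell-type separation (ARI, NMI, silhouette, cLISI, F1 of label
transfer) and batch mixing (batch entropy mixing score, iLISI). The
over-correction score is the complement of neighborhood label consistency
and catches the failure mode where genuinely distinct cell types are mixed —
a high batch-mixing score alone cannot distinguish good integration from
over-correction.

Conventions: clustering-based scores are computed on latent coordinates;
silhouette, batch entropy mixing and LISI on 2-D UMAP coordinates. Natural
logarithms throughout, with 0 * log 0 := 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn import metrics as skm
from sklearn.neighbors import NearestNeighbors


@dataclass
class MetricReport:
    """Named scalar metrics plus the protocol parameters that produced them."""

    ari: float | None = None
    nmi: float | None = None
    silhouette: float | None = None
    batch_entropy_mixing_raw: float | None = None
    batch_entropy_mixing: float | None = None
    ilisi: float | None = None
    clisi: float | None = None
    over_correction: float | None = None
    f1_macro: float | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _check_aligned(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and aligned per element")
    return a, b


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted pair-counting agreement: 1 for identical partitions,
    ~0 for independent ones."""
    labels_a, labels_b = _check_aligned(labels_a, labels_b)
    return float(skm.adjusted_rand_score(labels_a, labels_b))


def normalized_mutual_information(labels_a, labels_b) -> float:
    """Mutual information normalized by the geometric mean of the entropies.

    A constant partition has zero entropy; the score is then defined as 0
    (with a warning) rather than 0/0.
    """
    labels_a, labels_b = _check_aligned(labels_a, labels_b)
    if len(set(labels_a.tolist())) == 1 or len(set(labels_b.tolist())) == 1:
        warnings.warn("a partition with a single class has zero entropy; NMI := 0")
        return 0.0
    return float(skm.normalized_mutual_info_score(labels_a, labels_b, average_method="geometric"))


def f1_macro(true_labels, predicted_labels) -> float:
    """Unweighted mean over classes of per-class F1."""
    true_labels, predicted_labels = _check_aligned(true_labels, predicted_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(skm.f1_score(true_labels, predicted_labels, average="macro"))


def silhouette_on_embedding(coords_2d, cell_type_labels) -> float:
    """Mean silhouette (b - a) / max(a, b) on the 2-D embedding coordinates.

    Degenerate geometry (a = b = 0) contributes 0 by the 0/0 guard; singleton
    clusters likewise score 0.
    """
    coords_2d = np.asarray(coords_2d, dtype=np.float64)
    labels = np.asarray(cell_type_labels).astype(str)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 cell types for a silhouette score")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = skm.silhouette_samples(coords_2d, labels)
    vals = np.nan_to_num(vals, nan=0.0)
    return float(vals.mean())


def common_type_mask(batch_labels, cell_type_labels) -> np.ndarray:
    """True for cells whose type occurs in at least two batches.

    Batch mixing is only meaningful over cell types shared between batches;
    batch-specific types are excluded so that keeping them separate (the
    correct behaviour) is not punished as poor mixing.
    """
    batch_labels = np.asarray(batch_labels).astype(str)
    cell_type_labels = np.asarray(cell_type_labels).astype(str)
    mask = np.zeros(batch_labels.size, dtype=bool)
    for t in set(cell_type_labels.tolist()):
        rows = cell_type_labels == t
        if len(set(batch_labels[rows].tolist())) >= 2:
            mask |= rows
    return mask


def batch_entropy_mixing(
    coords,
    batch_labels,
    common_mask: np.ndarray | None = None,
    n_probes: int = 30,
    n_neighbors: int = 30,
    n_iterations: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Neighborhood entropy of batch composition around random probe cells.

    Protocol: compute global batch proportions P_i; per iteration draw
    ``n_probes`` probe cells (without replacement) and take each probe's
    ``n_neighbors`` nearest cells (the probe itself included); form the
    neighborhood batch proportions p_i, correct them to
    p_i' = (p_i / P_i) / sum(p_i / P_i), and accumulate the regional entropy
    E = sum p_i' log p_i'. The raw score is the mean of E over probes and
    iterations (0 at complete separation, log(1/n_batches) at perfect
    mixing); the rescaled score is -raw / log(n_batches), in [0, 1] with
    high = well mixed.

    When a mask of common cell types is given, only masked cells are used,
    both as probes and as neighbors.
    """
    coords = np.asarray(coords, dtype=np.float64)
    batch_labels = np.asarray(batch_labels).astype(str)
    if common_mask is not None:
        common_mask = np.asarray(common_mask, dtype=bool)
        lost = set(batch_labels.tolist()) - set(batch_labels[common_mask].tolist())
        if lost:
            raise ValueError(
                f"common-type mask removed whole batch(es) {sorted(lost)}; "
                f"surviving: {sorted(set(batch_labels[common_mask].tolist()))}"
            )
        coords = coords[common_mask]
        batch_labels = batch_labels[common_mask]
    batches = sorted(set(batch_labels.tolist()))
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    n = coords.shape[0]
    k = min(n_neighbors, n)
    P = np.array([(batch_labels == b).mean() for b in batches])
    codes = np.searchsorted(batches, batch_labels)

    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    rng = np.random.default_rng(seed)
    entropies = []
    for _ in range(n_iterations):
        probes = rng.choice(n, size=min(n_probes, n), replace=False)
        _, idx = nn.kneighbors(coords[probes])
        for neigh in idx:
            counts = np.bincount(codes[neigh], minlength=len(batches))
            p = counts / counts.sum()
            corrected = p / P
            corrected /= corrected.sum()
            nz = corrected > 0
            entropies.append(float((corrected[nz] * np.log(corrected[nz])).sum()))
    raw = float(np.mean(entropies))
    rescaled = float(-raw / np.log(len(batches)))
    return raw, rescaled


def lisi(
    coords,
    labels,
    perplexity: float = 30.0,
    n_bisect: int = 60,
) -> tuple[np.ndarray, float]:
    """Local inverse Simpson's index per cell, and its mean.

    For each cell, neighborhood weights are a Gaussian kernel over its
    nearest neighbors (the cell itself included, 3x perplexity neighbors),
    with the bandwidth calibrated by bisection so the weight entropy equals
    log(perplexity). The per-label weight mass P(y | x_i) then gives
    LISI(x_i) = 1 / sum_y P(y | x_i)^2 — the effective number of labels in
    the neighborhood, between 1 and the number of label categories.

    iLISI uses batch labels (high = mixed); cLISI uses cell-type labels
    (low = types kept apart).
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels).astype(str)
    n = coords.shape[0]
    cats = sorted(set(labels.tolist()))
    codes = np.searchsorted(cats, labels)
    k = int(min(3 * perplexity, n))
    if n <= perplexity:
        warnings.warn("cell count <= perplexity; bandwidth calibration saturates")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, idx = nn.kneighbors(coords)  # self included at distance 0
    d2 = dist**2
    target = np.log(perplexity)
    values = np.empty(n)
    for i in range(n):
        di = d2[i]
        if di.max() <= 0:  # duplicate coordinates: bandwidth floor, uniform weights
            w = np.full(k, 1.0 / k)
        else:
            lo, hi = 0.0, None
            beta = 1.0 / (di.mean() + 1e-12)
            for _ in range(n_bisect):
                e = np.exp(-beta * di)
                s = e.sum()
                w = e / s
                nzw = w[w > 0]
                H = -(nzw * np.log(nzw)).sum()
                if abs(H - target) < 1e-10:
                    break
                if H > target:  # too flat -> narrow the kernel
                    lo = beta
                    beta = beta * 2 if hi is None else (beta + hi) / 2
                else:
                    hi = beta
                    beta = (lo + beta) / 2
        mass = np.bincount(codes[idx[i]], weights=w, minlength=len(cats))
        values[i] = 1.0 / (mass**2).sum()
    return values, float(values.mean())


def over_correction_score(coords, cell_type_labels, k: int = 30, seed: int = 0) -> float:
    """Fraction of k-nearest neighbors (self excluded) with a different type.

    0 when every neighborhood is pure (no erroneous mixing of cell types),
    1 when every neighbor of every cell has a different type. A negative
    index: higher is worse.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(cell_type_labels).astype(str)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    idx = idx[:, 1:]  # drop self
    same = labels[idx] == labels[:, None]
    return float(1.0 - same.mean())


def evaluate(
    latent_coords,
    umap_coords,
    batch_labels,
    cell_type_labels,
    cluster_labels=None,
    predicted_labels=None,
    over_correction_k: int = 30,
    seed: int = 0,
) -> MetricReport:
    """Full metric suite on an integrated embedding.

    ARI/NMI compare Leiden clusters with the true cell types on the latent
    coordinates; silhouette, batch entropy mixing and LISI are computed on
    the UMAP coordinates; the batch-mixing scores are restricted to cell
    types common to at least two batches. F1 requires transferred labels.
    """
    batch_labels = np.asarray(batch_labels).astype(str)
    cell_type_labels = np.asarray(cell_type_labels).astype(str)
    report = MetricReport(
        params={
            "over_correction_k": over_correction_k,
            "entropy_neighbors": 30,
            "entropy_probes": 30,
            "entropy_iterations": 10,
            "lisi_perplexity": 30,
            "seed": seed,
        }
    )
    if cluster_labels is not None:
        report.ari = adjusted_rand_index(cell_type_labels, cluster_labels)
        report.nmi = normalized_mutual_information(cell_type_labels, cluster_labels)
    report.silhouette = silhouette_on_embedding(umap_coords, cell_type_labels)
    mask = common_type_mask(batch_labels, cell_type_labels)
    if mask.any() and len(set(batch_labels[mask].tolist())) >= 2:
        raw, rescaled = batch_entropy_mixing(
            umap_coords, batch_labels, common_mask=mask, seed=seed
        )
        report.batch_entropy_mixing_raw = raw
        report.batch_entropy_mixing = rescaled
        _, report.ilisi = lisi(np.asarray(umap_coords)[mask], batch_labels[mask])
    _, report.clisi = lisi(umap_coords, cell_type_labels)
    report.over_correction = over_correction_score(
        latent_coords, cell_type_labels, k=over_correction_k, seed=seed
    )
    if predicted_labels is not None:
        report.f1_macro = f1_macro(cell_type_labels, predicted_labels)
    return report
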