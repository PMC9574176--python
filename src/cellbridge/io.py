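"""Readers and writers for the supported on-disk formats.

Counts travel as AnnData: H5AD directly, MTX triplets (matrix.mtx +
features/barcodes TSVs) and dense CSV/TSV (cells in rows) are converted on
read. Preprocessed matrices round-trip through H5AD with the per-batch
scaling record and the preprocessing parameters stored in ``uns``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData

from .preprocess import BATCH_KEY, PROVENANCE_KEY, SCALING_KEY


def read_counts(
    path: str | Path,
    batch_key: str = BATCH_KEY,
    batch_label: str | None = None,
) -> AnnData:
    """Read counts from H5AD, an MTX directory, or dense CSV/TSV.

    ``batch_label`` assigns a single batch label to every cell when the file
    itself carries none (e.g. one raw batch to be projected).
    """
    path = Path(path)
    if path.is_dir():
        adata = sc.read_mtx(path / "matrix.mtx").T  # MTX is features x cells
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
        adata.var_names = features[0].astype(str).values
        adata.obs_names = barcodes[0].astype(str).values
    elif path.suffix == ".h5ad":
        adata = sc.read_h5ad(path)
    elif path.suffix in (".csv", ".tsv", ".txt"):
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        adata = AnnData(
            X=df.values.astype(float),
            obs=pd.DataFrame(index=df.index.astype(str)),
            var=pd.DataFrame(index=df.columns.astype(str)),
        )
    else:
        raise ValueError(f"unsupported input format: {path}")
    if batch_label is not None:
        adata.obs[batch_key] = batch_label
    if batch_key not in adata.obs:
        raise ValueError(
            f"no {batch_key!r} column in obs; pass batch_label for single-batch data"
        )
    adata.obs[batch_key] = adata.obs[batch_key].astype(str)
    return adata


def write_scaled(adata: AnnData, path: str | Path) -> None:
    """Write a preprocessed matrix to H5AD, keeping scaling record + params."""
    adata.write_h5ad(Path(path))


def read_scaled(path: str | Path) -> AnnData:
    adata = sc.read_h5ad(Path(path))
    for key in (SCALING_KEY, PROVENANCE_KEY):
        if key not in adata.uns:
            raise ValueError(f"{path} lacks uns[{key!r}]; not a preprocessed matrix")
    if isinstance(adata.uns[SCALING_KEY], dict):  # h5ad may store the frame as a mapping
        adata.uns[SCALING_KEY] = pd.DataFrame(adata.uns[SCALING_KEY])
    return adata


def write_labels(path: str | Path, cell_ids, predicted, confidence) -> None:
    pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "predicted": np.asarray(predicted).astype(str),
            "confidence": np.asarray(confidence, dtype=float),
        }
    ).to_csv(Path(path), sep="\t", index=False)
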