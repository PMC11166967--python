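"""Gene-module discovery: variance-based gene selection, 2-D embedding and
density-based clustering of genes, plus over-representation annotation of
the resulting clusters.

The filter composition is uniqueness → variance: first drop genes whose
modal expression value occurs in more than ``max_identical_fraction`` of
the samples (strict >), then drop genes whose variance is strictly below
``min_variance``. Both operate on log2(normalized count + 1) by default in
the pipeline driver; the scale of the variance cut is a documented,
configurable choice. Embedding defaults to UMAP; a deterministic
principal-component projection is available behind the same contract.
Clustering uses hierarchical density-based clustering (HDBSCAN), which is
deterministic for fixed hyperparameters; isolated genes get the noise
label −1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from ._utils import ValidationError
from .enrichment import ora

logger = logging.getLogger(__name__)


def log_normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size factor + 1), the default scale for the filters."""
    sf = factors.loc[counts.columns].to_numpy()
    return np.log2(counts / sf[None, :] + 1.0)


def uniqueness_filter(matrix: pd.DataFrame,
                      max_identical_fraction: float = 0.25) -> pd.DataFrame:
    """Drop genes whose modal value frequency exceeds the cutoff (strict >).

    Values are rounded to 6 decimals before comparing, so "identical
    expression levels" on processed data tolerates float formatting noise.
    """
    if matrix.empty:
        raise ValidationError("empty expression matrix")
    x = np.round(matrix.to_numpy(dtype=float), 6)
    n = x.shape[1]
    modal = np.array([np.max(np.unique(row, return_counts=True)[1])
                      for row in x])
    keep = modal / n <= max_identical_fraction
    logger.info("uniqueness_filter: %d of %d genes retained",
                int(keep.sum()), len(matrix))
    return matrix.loc[keep]


def variance_filter(matrix: pd.DataFrame,
                    min_variance: float = 1.7) -> pd.DataFrame:
    """Keep genes with sample variance (ddof=1) ≥ ``min_variance``; the
    removal rule is strict "less than"."""
    if matrix.shape[1] < 2:
        raise ValidationError("variance filter needs >=2 samples")
    var = matrix.var(axis=1, ddof=1)
    keep = var >= min_variance
    logger.info("variance_filter: %d of %d genes retained",
                int(keep.sum()), len(matrix))
    return matrix.loc[keep]


def embed_genes(matrix: pd.DataFrame, method: str = "umap", seed: int = 0,
                n_neighbors: int = 15, min_dist: float = 0.1) -> pd.DataFrame:
    """2-D gene embedding (rows are genes).

    ``method="umap"`` runs UMAP with a fixed random state; ``method="pca"``
    is a deterministic principal-component projection behind the same
    contract. A fixed seed reproduces coordinates.

    Gene rows are z-scored first so that distances reflect co-variation
    across samples rather than baseline abundance differences.
    """
    if len(matrix) < 10:
        raise ValidationError("embedding needs at least 10 genes")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    if method == "umap":
        if len(matrix) <= n_neighbors:
            raise ValidationError(
                f"{len(matrix)} genes <= n_neighbors={n_neighbors}; reduce "
                "the neighborhood size"
            )
        import umap  # deferred: numba compilation is slow to import

        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=int(seed))
        coords = reducer.fit_transform(x)
    elif method == "pca":
        coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    else:
        raise ValidationError(f"unknown embedding method {method!r}")
    return pd.DataFrame(np.asarray(coords, dtype=float), index=matrix.index,
                        columns=["x", "y"])


def cluster_genes(embedding: pd.DataFrame,
                  min_cluster_size: int = 10) -> pd.Series:
    """Density-based hierarchical clustering of the embedded genes.

    Labels are remapped to be contiguous from 0 in order of first
    appearance; noise keeps the label −1. Identical inputs and
    hyperparameters reproduce identical labels.
    """
    if min_cluster_size < 2:
        raise ValidationError("min_cluster_size must be >= 2")
    if len(embedding) < min_cluster_size:
        return pd.Series(-1, index=embedding.index, name="cluster")
    raw = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(
        embedding[["x", "y"]].to_numpy(dtype=float))
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab == -1:
            labels[i] = -1
        else:
            labels[i] = mapping.setdefault(int(lab), len(mapping))
    return pd.Series(labels, index=embedding.index, name="cluster")


def annotate_clusters(assignment: pd.Series,
                      collections: list[dict], universe: list[str],
                      fdr_threshold: float = 0.05,
                      min_size: int = 0) -> dict[int, pd.DataFrame]:
    """Run over-representation analysis per cluster against each collection
    and keep annotations passing the FDR cut. Noise genes (label −1) are
    excluded from every query."""
    clusters = sorted(set(assignment) - {-1})
    if not clusters:
        raise ValidationError("no non-noise cluster to annotate")
    out: dict[int, pd.DataFrame] = {}
    for c in clusters:
        members = list(assignment.index[assignment == c])
        tables = []
        for coll in collections:
            if not coll:
                logger.warning("annotate_clusters: empty collection skipped")
                continue
            res = ora(members, universe, coll, min_size=min_size)
            res = res[res["padj"].notna() & (res["padj"] <= fdr_threshold)]
            tables.append(res)
        if tables:
            merged = pd.concat(tables, ignore_index=True)
            merged = merged.sort_values("padj", kind="mergesort")
            out[c] = merged.reset_index(drop=True)
        else:
            out[c] = pd.DataFrame(columns=["set", "size", "overlap",
                                           "pvalue", "padj", "genes"])
    return out


def module_pipeline(matrix: pd.DataFrame, *, max_identical_fraction: float
                    = 0.25, min_variance: float = 1.7, method: str = "umap",
                    seed: int = 0, n_neighbors: int = 15,
                    min_cluster_size: int = 10
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Filters (uniqueness then variance), embedding, clustering."""
    filtered = variance_filter(
        uniqueness_filter(matrix, max_identical_fraction), min_variance)
    emb = embed_genes(filtered, method=method, seed=seed,
                      n_neighbors=n_neighbors)
    labels = cluster_genes(emb, min_cluster_size=min_cluster_size)
    return emb, labels
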