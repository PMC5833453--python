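"""Clustering of region-by-sample matrices and expression integration.

Promoter-DMR methylation matrices are partitioned with seeded K-means
(K = 3 by default, k-means++ initialisation, best of several restarts by
within-cluster sum of squares); DMR methylation and gene-expression matrices
are ordered by agglomerative hierarchical clustering (average linkage on
Euclidean distances by default). Expression (FPKM) is converted to per-gene
Z-scores with the sample (n-1) standard deviation after removing genes with
no expression in any cell type; with only three cell types the n-1 choice is
material and is therefore fixed here rather than left to callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "kmeans_rows",
    "hierarchical_rows",
    "expression_zscore",
    "build_report_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: pd.Series               # row id -> cluster label in 1..k
    centroids: pd.DataFrame         # cluster label x sample columns
    inertia: float
    row_order: list                 # rows sorted by (cluster, row id)


def kmeans_rows(
    matrix: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 10
) -> ClusterAssignment:
    """Seeded K-means over matrix rows (squared Euclidean distance).

    Lloyd's algorithm with k-means++ initialisation, best of ``n_restarts``
    by within-cluster sum of squares. Cluster labels are 1..k; within each
    cluster, ``row_order`` lists rows sorted by identifier (so gene-named
    rows come out alphabetically per cluster). Deterministic given ``seed``.
    """
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} rows, got {len(matrix)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    raw = km.fit_predict(matrix.to_numpy(dtype=float))
    labels = pd.Series(raw + 1, index=matrix.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.columns,
                             index=pd.RangeIndex(1, k + 1, name="cluster"))
    order = sorted(matrix.index, key=lambda r: (labels[r], str(r)))
    return ClusterAssignment(labels=labels, centroids=centroids,
                             inertia=float(km.inertia_), row_order=order)


def hierarchical_rows(
    matrix: pd.DataFrame, method: str = "average", metric: str = "euclidean"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of matrix rows.

    Returns the SciPy linkage matrix and the dendrogram leaf order as row
    identifiers. Merge heights are non-decreasing for average linkage on
    Euclidean distances.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows")
    z = linkage(matrix.to_numpy(dtype=float), method=method, metric=metric)
    order = [matrix.index[i] for i in leaves_list(z)]
    return z, order


def expression_zscore(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression Z-scores across samples.

    Genes with zero FPKM in *all* samples are removed first; remaining genes
    are standardised as z = (x - mean) / sd with the n-1 denominator. Genes
    with zero variance but nonzero expression cannot be standardised and are
    removed with a logged count.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("Z-scores need at least two samples")
    nonzero = fpkm[(fpkm != 0).any(axis=1)]
    n_all_zero = len(fpkm) - len(nonzero)
    sd = nonzero.std(axis=1, ddof=1)
    flat = sd == 0
    if int(flat.sum()):
        logger.info("expression_zscore: removed %d zero-variance genes",
                    int(flat.sum()))
    kept = nonzero[~flat]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    z.attrs["n_all_zero_removed"] = n_all_zero
    z.attrs["n_zero_variance_removed"] = int(flat.sum())
    return z


def build_report_tables(
    dmrs: pd.DataFrame,
    expression_z: pd.DataFrame | None = None,
    clusters: ClusterAssignment | None = None,
    gene_column: str = "feature_names",
) -> dict[str, pd.DataFrame]:
    """Assemble tidy heatmap tables from DMR levels and expression Z-scores.

    Returns a dict with a region x sample methylation matrix (``methylation``,
    level_* columns of ``dmrs`` with cluster labels attached when provided)
    and, when expression is given, a gene x sample ``expression`` matrix
    restricted to genes referenced by the DMRs, plus a ``join_report`` with
    the matched/unmatched counts. Handles empty inputs without error.
    """
    level_cols = [c for c in dmrs.columns if c.startswith("level_")]
    meth = dmrs[["chrom", "start", "end"] + level_cols].copy()
    meth.index = [f"{c}:{s}-{e}" for c, s, e in
                  zip(dmrs["chrom"], dmrs["start"], dmrs["end"])]
    meth.index.name = "region"
    if clusters is not None:
        meth["cluster"] = clusters.labels.reindex(meth.index).to_numpy()
        meth = meth.loc[[r for r in clusters.row_order if r in meth.index]]
    out: dict[str, pd.DataFrame] = {"methylation": meth}

    if expression_z is not None:
        genes: list[str] = []
        if gene_column in dmrs.columns:
            for entry in dmrs[gene_column]:
                for token in str(entry).split(","):
                    token = token.split(":")[-1].split(".")[0]
                    if token:
                        genes.append(token)
        genes = sorted(set(genes))
        matched = [g for g in genes if g in expression_z.index]
        out["expression"] = expression_z.loc[matched]
        out["join_report"] = pd.DataFrame(
            {"n_genes_referenced": [len(genes)],
             "n_genes_matched": [len(matched)],
             "n_genes_unmatched": [len(genes) - len(matched)]}
        )
    return out
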