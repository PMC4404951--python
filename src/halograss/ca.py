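"""Correspondence analysis of the unigene x sample expression matrix.

CA decomposes the standardized chi-square residuals of a non-negative
matrix: with correspondence matrix P = X / grand_total, row masses r and
column masses c, the residual matrix S = (P - r c') / sqrt(r c') is
factored by SVD. Row principal coordinates place each unigene in a space
whose total inertia is the matrix's chi-square statistic over the grand
total; for four samples at most three non-trivial axes exist, so the gene
cloud lives inside a tetrahedron.

Four artificial "guide genes", each expressed in exactly one sample, are
appended before the decomposition. Their row profiles are the extreme
sample-specific patterns, so their coordinates mark the tetrahedron
summits, and a gene's position relative to the summits, edges, and center
summarizes which samples dominate its expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster

GUIDE_PREFIX = "guide_"


@dataclass
class CAEmbedding:
    """Row principal coordinates (first 3 axes) plus inertia decomposition."""

    coords: pd.DataFrame          # genes (incl. guides) x [dim1..dim3]
    singular_values: np.ndarray
    inertia_total: float
    inertia_shares: np.ndarray
    row_masses: pd.Series
    column_coords: pd.DataFrame   # samples x [dim1..dim3], standard coords
    summits: pd.DataFrame | None  # guide label (sample) x [dim1..dim3]

    @property
    def scale(self) -> float:
        """Mean summit-to-centroid distance; the embedding's length unit."""
        if self.summits is None or not len(self.summits):
            d = np.linalg.norm(self.coords.values, axis=1)
            return float(np.sqrt(np.mean(d ** 2)))
        return float(np.linalg.norm(self.summits.values, axis=1).mean())

    def to_tsv(self, path, descriptors: pd.DataFrame | None = None) -> None:
        out = self.coords.copy()
        if descriptors is not None:
            out = out.join(descriptors)
        out.to_csv(path, sep="\t", index_label="gene_id")


def add_guide_genes(expr: pd.DataFrame, magnitude: float | None = None
                    ) -> pd.DataFrame:
    """Append one sample-exclusive guide row per column.

    Each guide has ``magnitude`` in exactly one sample and 0 elsewhere.
    The default magnitude is the 99th percentile of row sums — large enough
    to pin the summits, small enough not to dominate total inertia. Summit
    geometry is insensitive to this choice because a guide's row *profile*
    (all mass in one column) does not depend on its magnitude.
    """
    if magnitude is None:
        magnitude = float(np.percentile(expr.sum(axis=1), 99))
        if magnitude <= 0:
            magnitude = 1.0
    if magnitude <= 0:
        raise ValueError("guide magnitude must be > 0")
    guides = pd.DataFrame(0.0, columns=expr.columns,
                          index=[GUIDE_PREFIX + s for s in expr.columns])
    if guides.index.duplicated().any() or guides.index.isin(expr.index).any():
        raise ValueError("duplicate guide labels")
    for s in expr.columns:
        guides.loc[GUIDE_PREFIX + s, s] = magnitude
    return pd.concat([expr, guides])


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 3
                            ) -> CAEmbedding:
    """Run CA on a non-negative gene x sample table.

    All-zero rows are dropped with a warning. Row principal coordinates
    and column standard coordinates (asymmetric map) are returned for the
    first ``n_axes`` axes; the per-axis inertia share is sigma_i^2 over the
    total inertia.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero rows")
        matrix = matrix.loc[nonzero]
        X = X[nonzero]
    total = X.sum()
    if total <= 0:
        raise ValueError("matrix grand total must be > 0")

    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    k = min(n_axes, X.shape[1] - 1, X.shape[0] - 1)
    k = max(k, 0)
    inertia_total = float((sv ** 2).sum())
    if inertia_total <= 1e-15:
        # independence model: every profile equals the column masses
        warnings.warn("degenerate embedding: zero inertia (rank 0)")
        sv = np.zeros(max(k, 1))
        row_coords = np.zeros((X.shape[0], max(k, 1)))
        col_coords = np.zeros((X.shape[1], max(k, 1)))
        shares = np.zeros(max(k, 1))
    else:
        sv = sv[:k]
        row_coords = (U[:, :k] * sv) / np.sqrt(r)[:, None]
        col_coords = Vt[:k].T / np.sqrt(c)[:, None]
        shares = sv ** 2 / inertia_total

    dims = [f"dim{i + 1}" for i in range(row_coords.shape[1])]
    coords = pd.DataFrame(row_coords, index=matrix.index, columns=dims)
    col_df = pd.DataFrame(col_coords, index=matrix.columns, columns=dims)
    guide_rows = [i for i in coords.index
                  if isinstance(i, str) and i.startswith(GUIDE_PREFIX)]
    summits = None
    if guide_rows:
        summits = coords.loc[guide_rows].copy()
        summits.index = [g[len(GUIDE_PREFIX):] for g in guide_rows]
    return CAEmbedding(coords=coords, singular_values=sv,
                       inertia_total=inertia_total, inertia_shares=shares,
                       row_masses=pd.Series(r, index=matrix.index),
                       column_coords=col_df, summits=summits)


def _point_segment_distance(p, a, b) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def describe_positions(emb: CAEmbedding, gene_subset=None,
                       theta_summit: float = 0.25, theta_edge: float = 0.15
                       ) -> pd.DataFrame:
    """Geometric descriptors of genes relative to the guide tetrahedron.

    For each gene: distance to the centroid (origin), nearest summit and
    distance, nearest edge (summit pair) and perpendicular distance to the
    edge segment, and a region label — summit-proximal if the summit
    distance is below ``theta_summit`` times the mean summit-centroid
    distance, else edge-proximal below ``theta_edge`` times the same scale,
    else midsection.
    """
    if emb.summits is None or len(emb.summits) < 2:
        raise ValueError("embedding has no guide summits")
    if gene_subset is None:
        gene_subset = [g for g in emb.coords.index
                       if not str(g).startswith(GUIDE_PREFIX)]
    unknown = [g for g in gene_subset if g not in emb.coords.index]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown[:5]}")

    scale = emb.scale
    summit_labels = list(emb.summits.index)
    S = emb.summits.values
    edges = list(combinations(range(len(summit_labels)), 2))
    rows = []
    for g in gene_subset:
        p = emb.coords.loc[g].values
        d_centroid = float(np.linalg.norm(p))
        d_summits = np.linalg.norm(S - p, axis=1)
        ns = int(np.argmin(d_summits))
        edge_d = [(_point_segment_distance(p, S[i], S[j]), i, j)
                  for i, j in edges]
        de, ei, ej = min(edge_d)
        if d_summits[ns] < theta_summit * scale:
            region = "summit-proximal"
        elif de < theta_edge * scale:
            region = "edge-proximal"
        else:
            region = "midsection"
        rows.append((g, d_centroid, summit_labels[ns], float(d_summits[ns]),
                     f"{summit_labels[ei]}-{summit_labels[ej]}", de, region))
    return pd.DataFrame(rows, columns=[
        "gene_id", "distance_to_centroid", "nearest_summit",
        "nearest_summit_distance", "nearest_edge", "edge_distance", "region",
    ]).set_index("gene_id")


def cluster_subset(emb: CAEmbedding, gene_subset, linkage_cut: float = 0.5,
                   fold_changes: pd.Series | None = None):
    """Average-linkage clustering of a gene subset in the 3-D coordinates.

    The dendrogram is cut at ``linkage_cut`` times the embedding scale.
    Returns ``(labels, summary)``: integer cluster labels per gene, and a
    per-cluster table with size, centroid coordinates, the centroid's
    region label, and (when ``fold_changes`` is given) the mean absolute
    log2 fold change of its members.
    """
    gene_subset = list(gene_subset)
    if len(gene_subset) < 2:
        raise ValueError("gene_subset must contain at least 2 genes")
    pts = emb.coords.loc[gene_subset].values
    Z = linkage(pts, method="average", metric="euclidean")
    labels = fcluster(Z, t=linkage_cut * emb.scale, criterion="distance")
    labels = pd.Series(labels, index=pd.Index(gene_subset, name="gene_id"),
                       name="cluster")

    rows = []
    for cl in sorted(set(labels)):
        members = labels.index[labels == cl]
        centroid = emb.coords.loc[members].mean(axis=0).values
        region = "unlabeled"
        if emb.summits is not None and len(emb.summits) >= 2:
            scale = emb.scale
            d_sum = np.linalg.norm(emb.summits.values - centroid, axis=1)
            edges = list(combinations(range(len(emb.summits)), 2))
            de = min(_point_segment_distance(
                centroid, emb.summits.values[i], emb.summits.values[j])
                for i, j in edges)
            if d_sum.min() < 0.25 * scale:
                region = "summit-proximal"
            elif de < 0.15 * scale:
                region = "edge-proximal"
            else:
                region = "midsection"
        mean_fc = np.nan
        if fold_changes is not None:
            fc = fold_changes.reindex(members).dropna()
            if len(fc):
                mean_fc = float(np.abs(np.log2(fc)).mean())
        rows.append((cl, len(members), *centroid, region, mean_fc))
    dims = list(emb.coords.columns)
    summary = pd.DataFrame(rows, columns=[
        "cluster", "size", *[f"centroid_{d}" for d in dims],
        "region", "mean_abs_log2_fold"]).set_index("cluster")
    return labels, summary
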