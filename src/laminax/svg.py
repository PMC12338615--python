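"""Spatially-variable-gene scoring and cross-sample rank aggregation.

Each sample is scored independently: genes pass a per-sample expression
filter, then get a spatial-autocorrelation score (Moran's I on the
symmetrized k-nearest-neighbour spot graph of log-normalized values) and a
dense rank.  Ranks are aggregated across samples by their mean, and a gene
is called "replicated" when it falls in the per-sample top ``top_cut`` in
at least ``min_samples`` samples.  Any per-sample scorer producing a rank
table can be substituted for the built-in one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .data_model import SpatialSample, log_normalize


def per_sample_gene_filter(sample: SpatialSample, min_count: int = 3,
                           min_prop: float = 0.005) -> SpatialSample:
    """Keep genes with >= min_count counts in >= ceil(min_prop * n) spots."""
    n = sample.n_spots
    thresh_spots = max(1, math.ceil(min_prop * n))
    counts = sample.assay.counts
    if sp.issparse(counts):
        n_ge = np.asarray((counts >= min_count).sum(axis=1)).ravel()
    else:
        n_ge = (counts >= min_count).sum(axis=1)
    keep = n_ge >= thresh_spots
    if not keep.any():
        raise ValueError("per-sample gene filter removed every gene")
    return sample.subset_genes(keep)


def _knn_weights(xy: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetrized, row-normalized k-nearest-neighbour weights."""
    n = xy.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(xy)
    A = nn.kneighbors_graph(xy, mode="connectivity")
    A = A.tolil()
    A.setdiag(0)
    A = A.tocsr()
    A = A.maximum(A.T)  # symmetrize: neighbour in either direction
    row_sums = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(row_sums > 0, 1.0 / row_sums, 0.0)
    return sp.diags(inv) @ A


def morans_i(values: np.ndarray, W: sp.spmatrix) -> np.ndarray:
    """Moran's I for each row of ``values`` on weight matrix ``W``.

    Constant rows are defined as 0 (degenerate; no spatial structure to
    measure).
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    n = V.shape[1]
    Z = V - V.mean(axis=1, keepdims=True)
    denom = (Z ** 2).sum(axis=1)
    S0 = W.sum()
    lag = Z @ W.T.toarray() if W.shape[0] <= 2000 else np.asarray((W @ Z.T).T)
    num = (Z * lag).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = (n / S0) * num / denom
    I[denom == 0] = 0.0
    return I


def spatial_variability_score(sample: SpatialSample, k_neighbors: int = 6,
                              mode: str = "cp10k") -> pd.DataFrame:
    """Score and rank genes by Moran's I of log-normalized expression.

    Rank 1 is the most spatially structured gene; ties are broken by mean
    expression (higher first) then lexicographic gene id.  Constant genes
    score 0 and carry a degenerate flag.
    """
    if sample.n_spots < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 spots")
    logexpr = log_normalize(sample.assay, mode).dense()
    W = _knn_weights(sample.xy, k_neighbors)
    score = morans_i(logexpr, W)
    meanexpr = logexpr.mean(axis=1)
    degenerate = logexpr.ptp(axis=1) == 0 if hasattr(logexpr, "ptp") else np.ptp(logexpr, axis=1) == 0
    tab = pd.DataFrame(
        {
            "gene_id": sample.assay.gene_ids,
            "score": score,
            "mean_expr": meanexpr,
            "degenerate": degenerate,
        }
    )
    tab = tab.sort_values(
        ["score", "mean_expr", "gene_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


@dataclass
class SVGResult:
    """Aggregated spatially-variable-gene table across samples."""

    table: pd.DataFrame  # gene_id, mean_rank, n_top_samples, replicated
    per_sample: dict     # sample_id -> rank table
    top_cut: int
    min_samples: int


def aggregate_svg(per_sample_results: dict, top_cut: int = 1000, min_samples: int = 2,
                  absent_rule: str = "penalize") -> SVGResult:
    """Combine per-sample rank tables into the replicated-gene ranking.

    ``mean_rank`` averages each gene's per-sample ranks; with the default
    ``absent_rule='penalize'`` a gene filtered out of a sample contributes
    that sample's G_s + 1 (one worse than last place), with
    ``'present_only'`` only samples containing the gene contribute.
    ``n_top_samples`` counts samples where the gene ranked <= top_cut, and
    a gene is replicated when that count reaches ``min_samples``.  The
    output orders replicated genes first, by mean rank ascending.
    """
    if len(per_sample_results) < 2:
        raise ValueError("need at least 2 samples to aggregate")
    if absent_rule not in ("penalize", "present_only"):
        raise ValueError("absent_rule must be 'penalize' or 'present_only'")
    all_genes = sorted({g for t in per_sample_results.values() for g in t["gene_id"]})
    idx = pd.Index(all_genes, name="gene_id")
    ranks = pd.DataFrame(index=idx, columns=list(per_sample_results), dtype=float)
    for sid, tab in per_sample_results.items():
        ranks.loc[tab["gene_id"].to_numpy(), sid] = tab["rank"].to_numpy(dtype=float)
        if absent_rule == "penalize":
            ranks[sid] = ranks[sid].fillna(len(tab) + 1)
    mean_rank = ranks.mean(axis=1, skipna=True)
    n_top = (ranks <= top_cut).sum(axis=1).astype(int)
    out = pd.DataFrame(
        {
            "gene_id": idx,
            "mean_rank": mean_rank.to_numpy(),
            "n_top_samples": n_top.to_numpy(),
            "replicated": (n_top >= min_samples).to_numpy(),
        }
    ).sort_values(
        ["replicated", "mean_rank", "gene_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return SVGResult(out, dict(per_sample_results), top_cut, min_samples)
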