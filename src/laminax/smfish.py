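"""Per-cell smFISH quantification.

Cells positive for an anchor gene (a layer marker delimiting the band of
interest) are found by k-means at k=3 on copy count and signal intensity,
keeping the top clusters; analysis is restricted to a polygon around the
anchor-positive cells; copy counts are normalized by relative cell area;
each gene's expressors are called per sample by a two-component Gaussian
mixture; and coexpression is summarized by conditional call proportions
and Spearman correlations of scaled copies.

Cell tables are plain DataFrames with columns ``cell_id, x, y, area`` and,
per gene g, ``{g}_copies`` and ``{g}_intensity``; derived columns are
added in place (``anchor_positive``, ``in_polygon``, ``{g}_scaled``,
``{g}_expressing``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from shapely.geometry import MultiPoint, Point, Polygon
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture


def anchor_gate(cells: pd.DataFrame, anchor_gene: str, k: int = 3, n_keep: int = 2,
                standardize: bool = True, seed: int = 0) -> tuple[np.ndarray, dict]:
    """Gate anchor-positive cells by k-means on (copy count, intensity).

    Features are standardized to unit variance by default; clusters are
    ranked by their centroid copy count (original scale) and the top
    ``n_keep`` clusters called positive.  Returns the positive flags and
    the implied minimum copy count / intensity among positives.
    """
    copies = cells[f"{anchor_gene}_copies"].to_numpy(dtype=float)
    intens = cells[f"{anchor_gene}_intensity"].to_numpy(dtype=float)
    F = np.column_stack([copies, intens])
    sds = F.std(axis=0)
    if np.all(sds == 0) or len(cells) < k:
        raise ValueError("degenerate anchor data: need >= k cells with nonzero variance")
    Fs = F / np.where(sds > 0, sds, 1.0) if standardize else F
    km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(Fs)
    lab = km.labels_
    centroid_copies = np.array([copies[lab == c].mean() for c in range(k)])
    top = np.argsort(-centroid_copies)[:n_keep]
    positive = np.isin(lab, top)
    implied = {
        "min_copies": float(copies[positive].min()),
        "min_intensity": float(intens[positive].min()),
    }
    cells["anchor_positive"] = positive
    return positive, implied


def polygon_restrict(cells: pd.DataFrame, polygon=None) -> np.ndarray:
    """Flag cells inside a polygon (boundary counts as inside).

    ``polygon`` is a closed vertex list/array; with None ('auto' mode) the
    convex hull of the anchor-positive cells is used (``anchor_gate`` must
    have run).  Self-intersecting manual polygons are rejected.
    """
    if polygon is None:
        if "anchor_positive" not in cells:
            raise ValueError("auto polygon requires anchor_gate to have been applied")
        pts = cells.loc[cells["anchor_positive"], ["x", "y"]].to_numpy()
        if len(pts) < 3:
            raise ValueError("need >= 3 anchor-positive cells for an automatic hull")
        poly = MultiPoint([tuple(p) for p in pts]).convex_hull
    else:
        poly = Polygon([tuple(p) for p in np.asarray(polygon, dtype=float)])
        if not poly.is_valid:
            raise ValueError("polygon is invalid (self-intersecting?)")
    inside = np.array(
        [poly.covers(Point(x, y)) for x, y in cells[["x", "y"]].to_numpy()], dtype=bool
    )
    cells["in_polygon"] = inside
    return inside


def scale_by_area(cells: pd.DataFrame, genes, mode: str = "divide") -> pd.DataFrame:
    """Normalize copy counts by relative cell area.

    The default reading divides each cell's copies by area / median(area)
    (larger cells down-weighted); ``mode='multiply'`` applies the
    multiplicative reading instead.  The median is taken over in-polygon
    cells when the flag exists, else over all cells.
    """
    if mode not in ("divide", "multiply"):
        raise ValueError("mode must be 'divide' or 'multiply'")
    area = cells["area"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    ref = cells["in_polygon"].to_numpy(bool) if "in_polygon" in cells else np.ones(len(cells), bool)
    med = float(np.median(area[ref])) if ref.any() else float(np.median(area))
    rel = area / med
    for g in genes:
        copies = cells[f"{g}_copies"].to_numpy(dtype=float)
        cells[f"{g}_scaled"] = copies / rel if mode == "divide" else copies * rel
    return cells


def gmm_expressor_call(values, seed: int = 0) -> tuple[np.ndarray, dict]:
    """Call expressors by a 1-D two-component Gaussian mixture.

    EM with k-means initialization, 10 restarts, tol 1e-8 and a variance
    floor of 1e-6; a cell is expressing when its posterior for the
    higher-mean component is >= 0.5.  All-identical input is degenerate:
    every cell is non-expressing and the parameter dict carries a flag.
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.shape[0] < 10:
        raise ValueError("need at least 10 cells")
    if np.ptp(v) == 0:
        return np.zeros(v.shape[0], dtype=bool), {"degenerate": True}
    gm = GaussianMixture(
        n_components=2, n_init=10, tol=1e-8, reg_covar=1e-6, random_state=seed
    ).fit(v)
    hi = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(v)[:, hi]
    calls = post >= 0.5
    params = {
        "degenerate": False,
        "means": gm.means_.ravel().tolist(),
        "sds": np.sqrt(gm.covariances_.ravel()).tolist(),
        "weights": gm.weights_.tolist(),
        "high_component": hi,
    }
    return calls, params


def call_expressors(cells: pd.DataFrame, genes, seed: int = 0) -> dict:
    """Per-gene GMM calls on scaled copies of in-polygon cells.

    Adds ``{g}_expressing`` columns (False outside the polygon) and
    returns the per-gene mixture parameters.
    """
    mask = cells["in_polygon"].to_numpy(bool) if "in_polygon" in cells else np.ones(len(cells), bool)
    params = {}
    for g in genes:
        col = f"{g}_scaled" if f"{g}_scaled" in cells else f"{g}_copies"
        calls, par = gmm_expressor_call(cells.loc[mask, col].to_numpy(), seed=seed)
        full = np.zeros(len(cells), dtype=bool)
        full[np.flatnonzero(mask)] = calls
        cells[f"{g}_expressing"] = full
        params[g] = par
    return params


def coexpression_stats(cells: pd.DataFrame, genes) -> dict:
    """Coexpression summaries over in-polygon cells of one sample.

    Returns the proportions of cells expressing exactly two and all of
    the genes, the conditional matrix P(expressing j | expressing i)
    (rows with zero expressors of i are missing), and the pairwise
    Spearman correlation of scaled copies (average-rank ties).
    """
    mask = cells["in_polygon"].to_numpy(bool) if "in_polygon" in cells else np.ones(len(cells), bool)
    sub = cells.loc[mask]
    calls = np.column_stack([sub[f"{g}_expressing"].to_numpy(bool) for g in genes])
    n_expr = calls.sum(axis=1)
    m = len(genes)
    conditional = pd.DataFrame(np.nan, index=list(genes), columns=list(genes))
    for i, gi in enumerate(genes):
        ni = calls[:, i].sum()
        if ni == 0:
            continue
        for j, gj in enumerate(genes):
            conditional.loc[gi, gj] = float((calls[:, i] & calls[:, j]).sum() / ni)
    spear = pd.DataFrame(np.eye(m), index=list(genes), columns=list(genes))
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if i < j:
                col_i = f"{gi}_scaled" if f"{gi}_scaled" in sub else f"{gi}_copies"
                col_j = f"{gj}_scaled" if f"{gj}_scaled" in sub else f"{gj}_copies"
                rho = spearmanr(sub[col_i], sub[col_j]).statistic
                spear.loc[gi, gj] = spear.loc[gj, gi] = float(rho)
    return {
        "prop_exactly_two": float((n_expr == 2).mean()) if len(sub) else np.nan,
        "prop_all": float((n_expr == m).mean()) if len(sub) else np.nan,
        "conditional": conditional,
        "spearman": spear,
        "n_cells": int(len(sub)),
    }


def average_conditional(per_sample: list) -> pd.DataFrame:
    """Average conditional matrices across a sample group (NaN-aware)."""
    mats = [s["conditional"] for s in per_sample]
    return pd.concat(mats).groupby(level=0).mean().loc[mats[0].index, mats[0].columns]
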