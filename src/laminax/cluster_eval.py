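"""Internal-validity metrics for choosing a spatial clustering resolution.

Neighbour purity measures, for each observation, the fraction of its k
nearest neighbours in the embedding that share its label; H+ estimates the
probability that a randomly chosen within-cluster pair of observations is
farther apart than a randomly chosen between-cluster pair (0 = perfectly
compact and separated, 0.5 = labels unrelated to geometry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors


@dataclass
class ClusterEval:
    purity: pd.DataFrame
    mean_purity: float
    h_plus: float
    n_pairs_sampled: int
    seed: int


def neighbor_purity(embedding: np.ndarray, labels, k: int = 50) -> tuple[pd.DataFrame, float]:
    """Per-cluster mean same-label fraction among k nearest neighbours.

    Reported as the same-label fraction, so 1 means a perfectly pure
    neighbourhood.  Clusters with fewer than 2 members carry a
    ``small_cluster`` flag.
    """
    X = np.asarray(embedding, dtype=float)
    lab = np.asarray(labels)
    n = X.shape[0]
    if lab.shape[0] != n:
        raise ValueError("labels length must match embedding rows")
    if k >= n:
        raise ValueError("k must be smaller than the number of observations")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop self
    same = (lab[idx] == lab[:, None]).mean(axis=1)
    rows = []
    for c in pd.unique(lab):
        members = lab == c
        rows.append(
            {
                "cluster": c,
                "purity": float(same[members].mean()),
                "n": int(members.sum()),
                "impurity": float(1.0 - same[members].mean()),
                "small_cluster": bool(members.sum() < 2),
            }
        )
    tab = pd.DataFrame(rows)
    return tab, float(tab["purity"].mean())


def h_plus(embedding_or_distances, labels, n_pairs: int = 100_000,
           seed: int = 0, method: str = "auto") -> tuple[float, int]:
    """Estimate P(within-cluster distance > between-cluster distance).

    Accepts either an observations x features embedding or a precomputed
    square distance matrix.  With ``method='auto'`` the probability is
    computed exactly (by enumerating all within/between distance pairs,
    counting ties half) when the total number of observation pairs is at
    most ``2 * n_pairs``; otherwise ``n_pairs`` independent within/between
    distance pairs are sampled with the given seed.  ``'exact'`` and
    ``'sample'`` force either path.
    """
    if method not in ("auto", "exact", "sample"):
        raise ValueError("method must be auto, exact or sample")
    lab = np.asarray(labels)
    if len(pd.unique(lab)) < 2:
        raise ValueError("need at least 2 clusters")
    X = np.asarray(embedding_or_distances, dtype=float)
    if X.ndim == 2 and X.shape[0] == X.shape[1] and np.allclose(X, X.T) and np.allclose(np.diag(X), 0):
        D = X
    else:
        D = squareform(pdist(X))
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    within_mask = lab[iu] == lab[ju]
    d_within = D[iu[within_mask], ju[within_mask]]
    d_between = D[iu[~within_mask], ju[~within_mask]]
    if d_within.size == 0 or d_between.size == 0:
        raise ValueError("degenerate labelling: no within or no between pairs")

    exact = method == "exact" or (method == "auto" and iu.size <= 2 * n_pairs)
    if exact:
        # exact: count between-distances strictly below each within-distance
        db = np.sort(d_between)
        lt = np.searchsorted(db, d_within, side="left")
        le = np.searchsorted(db, d_within, side="right")
        total = lt.sum() + 0.5 * (le - lt).sum()
        return float(total / (d_within.size * d_between.size)), int(
            d_within.size * d_between.size
        )
    rng = np.random.default_rng(seed)
    w = d_within[rng.integers(0, d_within.size, n_pairs)]
    b = d_between[rng.integers(0, d_between.size, n_pairs)]
    est = (w > b).mean() + 0.5 * (w == b).mean()
    return float(est), n_pairs


def evaluate_clustering(embedding, labels, k: int = 50, n_pairs: int = 100_000,
                        seed: int = 0) -> ClusterEval:
    tab, mean_p = neighbor_purity(embedding, labels, k=k)
    h, n_used = h_plus(embedding, labels, n_pairs=n_pairs, seed=seed)
    return ClusterEval(tab, mean_p, h, n_used, seed)
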