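"""Cross-validated NMF and transfer of patterns across datasets.

The snRNA-seq log-normalized matrix is factorized as X ~ W H with
non-negative loadings W (genes x k) and weights H (k x observations) by
HALS-style alternating updates minimizing the Frobenius loss.  The rank is
chosen by speckled cross-validation: a random fraction of entries is held
out, the model is fit on the rest with EM-style imputation, and the rank
minimizing held-out error wins.  Patterns correlated with technical
covariates (library size, mito rate, donor, sex dummies) are flagged and
excluded from annotation; the remaining patterns are assigned to cell
types by mean weight, and transferred into any other gene x observation
matrix by non-negative least squares on the shared gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_model import CountAssay, LogNormMatrix
from .pseudobulk import DEStats, pairwise_model, pseudobulk


def _coerce_matrix(X) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if isinstance(X, LogNormMatrix):
        return X.dense(), X.gene_ids, X.obs_ids
    return np.asarray(X, dtype=float), None, None


@dataclass
class NMFModel:
    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: np.ndarray
    seed: int
    gene_ids: np.ndarray | None = None
    obs_ids: np.ndarray | None = None
    technical: np.ndarray | None = None  # filled by technical_filter
    pattern_meta: pd.DataFrame | None = None

    @property
    def pattern_names(self) -> list:
        return [f"NMF{i + 1}" for i in range(self.k)]


@dataclass
class ProjectionResult:
    H_new: np.ndarray
    genes_used: list
    dropped_genes: dict


def _hals_sweep(X, W, H, l1_w: float = 0.0):
    """One full HALS pass over W columns then H rows (in place).

    ``l1_w > 0`` soft-thresholds each loading column by ``l1_w`` (in
    unit-L2-loading units) after its least-squares update and renormalizes
    columns of W to unit L2 with the scale absorbed into H.  This breaks
    the additive shift degeneracy of NMF (a flat baseline floor shared by
    a pattern and the global profile) in favour of gene-sparse patterns.
    """
    HHt = H @ H.T
    XHt = X @ H.T
    k = W.shape[1]
    for j in range(k):
        denom = HHt[j, j]
        if denom <= 1e-12:
            continue
        w = np.maximum(0.0, W[:, j] + (XHt[:, j] - W @ HHt[:, j]) / denom)
        if l1_w > 0:
            norm = np.linalg.norm(w)
            if norm > 0:
                w = np.maximum(0.0, w - l1_w * norm)
        W[:, j] = w
    if l1_w > 0:
        norms = np.linalg.norm(W, axis=0)
        pos = norms > 0
        W[:, pos] /= norms[pos]
        H[pos, :] *= norms[pos, None]
    WtW = W.T @ W
    WtX = W.T @ X
    for j in range(k):
        denom = WtW[j, j]
        if denom <= 1e-12:
            continue
        H[j, :] = np.maximum(0.0, H[j, :] + (WtX[j, :] - WtW[j, :] @ H) / denom)
    return W, H


def nmf_fit(X, k: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
            l1_w: float = 0.0) -> NMFModel:
    """Frobenius NMF by HALS with seeded uniform initialization.

    Stops when the relative loss change drops below ``tol`` or after
    ``max_iter`` sweeps.  Columns of W are normalized to unit L2 at the
    end, with the scale absorbed into H.  The objective trace records the
    reconstruction loss per sweep; for the plain fit (``l1_w = 0``) it is
    non-increasing.  ``l1_w > 0`` soft-thresholds the loadings each sweep
    (sparse, marker-concentrated patterns; see ``_hals_sweep``), at the
    cost of strict monotonicity of the unpenalized loss.
    """
    Xm, gene_ids, obs_ids = _coerce_matrix(X)
    if np.any(Xm < 0):
        raise ValueError("X must be non-negative")
    G, n = Xm.shape
    if k >= min(G, n):
        raise ValueError(f"k={k} must be smaller than min(dims)={min(G, n)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(Xm.mean(), 1e-12) / k)
    W = rng.uniform(0.0, 1.0, (G, k)) * scale
    H = rng.uniform(0.0, 1.0, (k, n)) * scale
    trace = []
    prev = None
    for _ in range(max_iter):
        W, H = _hals_sweep(Xm, W, H, l1_w)
        loss = float(np.linalg.norm(Xm - W @ H) ** 2)
        trace.append(loss)
        if prev is not None and prev > 0 and abs(prev - loss) / prev < tol:
            break
        prev = loss
    norms = np.linalg.norm(W, axis=0)
    pos = norms > 0
    W[:, pos] /= norms[pos]
    H[pos, :] *= norms[pos, None]
    return NMFModel(W, H, k, np.asarray(trace), seed, gene_ids, obs_ids)


def cross_validate_rank(X, ranks, mask_fraction: float = 0.05, n_reps: int = 3,
                        seed: int = 0, max_iter: int = 200, tol: float = 1e-5,
                        max_mask_retries: int = 10) -> tuple[pd.DataFrame, int]:
    """Select the NMF rank by speckled-holdout cross-validation.

    For each repetition a seeded random ``mask_fraction`` of entries is
    held out (redrawn, up to ``max_mask_retries`` times, if any row or
    column would lose all observed entries).  The model is fit on observed
    entries with masked entries imputed by the current reconstruction each
    sweep; the held-out mean squared error, averaged over repetitions, is
    reported per rank, and the argmin (ties to the smaller rank) selected.
    """
    Xm, _, _ = _coerce_matrix(X)
    ranks = list(ranks)
    if not ranks:
        raise ValueError("ranks must be nonempty")
    rng = np.random.default_rng(seed)
    errors = np.zeros((len(ranks), n_reps))
    for rep in range(n_reps):
        for _ in range(max_mask_retries):
            mask = rng.random(Xm.shape) < mask_fraction
            if mask.all(axis=1).any() or mask.all(axis=0).any():
                continue
            if mask.any():
                break
        else:
            raise ValueError("could not draw a mask keeping every row and column observed")
        fit_seed = int(rng.integers(0, 2 ** 31 - 1))
        for ri, k in enumerate(ranks):
            errors[ri, rep] = _masked_holdout_error(
                Xm, mask, k, fit_seed, max_iter, tol
            )
    mean_err = errors.mean(axis=1)
    table = pd.DataFrame({"rank": ranks, "heldout_mse": mean_err})
    selected = int(table.loc[table["heldout_mse"].idxmin(), "rank"])
    # ties (within numerical noise) resolve to the smaller rank
    best = table["heldout_mse"].min()
    tied = table[np.isclose(table["heldout_mse"], best, rtol=1e-12, atol=0)]
    selected = int(tied["rank"].min())
    return table, selected


def _masked_holdout_error(Xm, mask, k, seed, max_iter, tol) -> float:
    rng = np.random.default_rng(seed)
    G, n = Xm.shape
    X_work = Xm.copy()
    obs_mean = Xm[~mask].mean()
    X_work[mask] = obs_mean
    scale = np.sqrt(max(obs_mean, 1e-12) / k)
    W = rng.uniform(0.0, 1.0, (G, k)) * scale
    H = rng.uniform(0.0, 1.0, (k, n)) * scale
    prev = None
    for _ in range(max_iter):
        W, H = _hals_sweep(X_work, W, H)
        recon = W @ H
        X_work[mask] = recon[mask]  # EM-style imputation
        loss = float(((Xm[~mask] - recon[~mask]) ** 2).sum())
        if prev is not None and prev > 0 and abs(prev - loss) / prev < tol:
            break
        prev = loss
    recon = W @ H
    return float(((Xm[mask] - recon[mask]) ** 2).mean())


# ----------------------------------------------------------------------
# Pattern annotation and technical filtering
# ----------------------------------------------------------------------

def technical_filter(model: NMFModel, covariates: pd.DataFrame,
                     threshold: float = 0.5) -> pd.Series:
    """Flag patterns whose weights correlate with technical covariates.

    Numeric columns are used as-is; categorical columns are expanded into
    one 0/1 dummy per level.  A pattern is technical when the maximum
    absolute Pearson correlation over covariates reaches ``threshold``.
    Zero-variance patterns or covariates give r = 0.
    """
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
            cols[name] = col.to_numpy(dtype=float)
        else:
            for lev in pd.unique(col.astype(str)):
                cols[f"{name}={lev}"] = (col.astype(str) == lev).to_numpy(dtype=float)
    max_r = np.zeros(model.k)
    for j in range(model.k):
        h = model.H[j, :]
        if np.std(h) == 0:
            continue
        for v in cols.values():
            if np.std(v) == 0:
                continue
            r = abs(float(np.corrcoef(h, v)[0, 1]))
            max_r[j] = max(max_r[j], r)
    flags = pd.Series(max_r >= threshold, index=model.pattern_names, name="technical")
    model.technical = flags.to_numpy()
    return flags


def annotate_patterns(model: NMFModel, cell_labels, n_top_genes: int = 10) -> pd.DataFrame:
    """Assign each cell type its top (non-technical) pattern.

    The mean pattern weight within each cell type is computed; per cell
    type the non-technical pattern with the highest mean wins, ties broken
    by the higher specificity ratio (top mean / second mean) and then the
    lower pattern index.  Each pattern records its top loading genes.
    Returns the pattern_meta table (also stored on the model); the
    cell-type x pattern mean matrix is in ``model.mean_by_type``.
    """
    labels = np.asarray(cell_labels)
    if labels.shape[0] != model.H.shape[1]:
        raise ValueError("cell_labels length must match observations")
    types = list(pd.unique(labels))
    mean_by_type = pd.DataFrame(
        {t: model.H[:, labels == t].mean(axis=1) for t in types},
        index=model.pattern_names,
    )
    technical = model.technical if model.technical is not None else np.zeros(model.k, bool)

    def _specificity(j: int) -> float:
        vals = np.sort(mean_by_type.iloc[j].to_numpy())[::-1]
        return float(vals[0] / vals[1]) if len(vals) > 1 and vals[1] > 0 else np.inf

    top_pattern = {}
    for t in types:
        col = mean_by_type[t].to_numpy().copy()
        col[technical] = -np.inf
        best = col.max()
        cand = np.flatnonzero(col == best)
        if len(cand) > 1:
            spec = np.array([_specificity(j) for j in cand])
            cand = cand[spec == spec.max()]
        top_pattern[t] = model.pattern_names[int(cand.min())]

    gene_ids = model.gene_ids if model.gene_ids is not None else np.arange(model.W.shape[0])
    rows = []
    for j, name in enumerate(model.pattern_names):
        order = np.argsort(-model.W[:, j], kind="stable")[:n_top_genes]
        assigned = sorted(t for t, pat in top_pattern.items() if pat == name)
        rows.append(
            {
                "pattern": name,
                "technical": bool(technical[j]),
                "assigned_types": ",".join(map(str, assigned)),
                "top_genes": ",".join(map(str, np.asarray(gene_ids)[order])),
            }
        )
    meta = pd.DataFrame(rows).set_index("pattern")
    model.pattern_meta = meta
    model.mean_by_type = mean_by_type
    model.top_pattern_by_type = pd.Series(top_pattern)
    return meta


# ----------------------------------------------------------------------
# Transfer by non-negative least squares
# ----------------------------------------------------------------------

def project_patterns(model: NMFModel, X_new, gene_ids_new=None) -> ProjectionResult:
    """Project fixed loadings into a new dataset by per-observation NNLS.

    Rows of W and of the new matrix are restricted to the shared gene set
    in a common order; each new observation's weights solve
    min_{h>=0} ||x - W h||^2.  Deterministic.
    """
    Xm, gids, _ = _coerce_matrix(X_new)
    if gene_ids_new is not None:
        gids = np.asarray(gene_ids_new, dtype=object)
    if gids is None or model.gene_ids is None:
        if Xm.shape[0] != model.W.shape[0]:
            raise ValueError("no gene ids available and row counts differ")
        gids = model.gene_ids if model.gene_ids is not None else np.arange(Xm.shape[0])
        model_gids = gids
    else:
        model_gids = model.gene_ids
    pos_model = {g: i for i, g in enumerate(np.asarray(model_gids))}
    pos_new = {g: i for i, g in enumerate(np.asarray(gids))}
    shared = [g for g in np.asarray(model_gids) if g in pos_new]
    if not shared:
        raise ValueError(
            f"empty gene intersection; model genes like {list(pos_model)[:3]}, "
            f"new genes like {list(pos_new)[:3]}"
        )
    Wm = model.W[[pos_model[g] for g in shared], :]
    Xs = Xm[[pos_new[g] for g in shared], :]
    H_new = np.empty((model.k, Xs.shape[1]))
    for j in range(Xs.shape[1]):
        H_new[:, j], _ = nnls(Wm, Xs[:, j])
    dropped = {
        "model_only": int(len(model_gids) - len(shared)),
        "new_only": int(len(gids) - len(shared)),
    }
    return ProjectionResult(H_new, list(shared), dropped)


# ----------------------------------------------------------------------
# Pattern-positive spot DE and summaries
# ----------------------------------------------------------------------

def nmf_positive_de(assay: CountAssay, h_a: np.ndarray, h_b: np.ndarray,
                    sample_key: str = "sample", eps: float = 0.0,
                    min_obs: int = 5, covariates: list = ("donor",),
                    name_a: str = "A", name_b: str = "B") -> tuple[DEStats, dict]:
    """Pairwise DE between spots positive for one pattern vs another.

    A spot is in class A when h_a > eps and h_b <= eps (class B
    symmetric); doubly-positive spots are excluded and counted in the
    report.  The two classes are pseudobulked by sample and contrasted
    with the pairwise moderated-t model (logFC = A - B).
    """
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    if h_a.shape[0] != assay.n_obs or h_b.shape[0] != assay.n_obs:
        raise ValueError("pattern weights must align with assay observations")
    in_a = (h_a > eps) & (h_b <= eps)
    in_b = (h_b > eps) & (h_a <= eps)
    both = (h_a > eps) & (h_b > eps)
    report = {
        "n_a": int(in_a.sum()),
        "n_b": int(in_b.sum()),
        "n_double_positive": int(both.sum()),
        "n_neither": int((~(in_a | in_b | both)).sum()),
    }
    if report["n_a"] == 0 or report["n_b"] == 0:
        raise ValueError(f"empty pattern class: {report}")
    sub = assay.subset_obs(in_a | in_b)
    cls = np.where(in_a[in_a | in_b], name_a, name_b)
    sub.obs_meta = sub.obs_meta.copy()
    sub.obs_meta["nmf_class"] = cls
    pb, _ = pseudobulk(sub, "nmf_class", sample_key, min_obs=min_obs)
    stats = pairwise_model(pb, name_a, name_b, covariates=covariates)
    return stats, report


def fraction_nonzero_by_group(h: np.ndarray, group_labels, sample_labels,
                              eps: float = 0.0) -> pd.DataFrame:
    """Per-sample fraction of group observations with pattern weight > eps.

    A (sample, group) cell with no observations is missing (NaN), not 0.
    """
    df = pd.DataFrame(
        {"h": np.asarray(h, float), "group": np.asarray(group_labels),
         "sample": np.asarray(sample_labels)}
    )
    out = df.groupby(["sample", "group"], observed=True)["h"].apply(
        lambda v: float((v > eps).mean())
    )
    return out.unstack("group")


def mean_weight_by_group(h: np.ndarray, group_labels, sample_labels) -> pd.DataFrame:
    """Per-sample mean pattern weight within each group (NaN when empty)."""
    df = pd.DataFrame(
        {"h": np.asarray(h, float), "group": np.asarray(group_labels),
         "sample": np.asarray(sample_labels)}
    )
    return df.groupby(["sample", "group"], observed=True)["h"].mean().unstack("group")
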