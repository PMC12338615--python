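"""Pseudobulking and moderated-t differential expression.

Counts are summed over all observations sharing a (group, sample) pair to
form bulk-like columns; models act on log2(CPM + 1) of these columns.  The
enrichment model tests, per group, whether expression in that group's
columns exceeds the rest (one-vs-rest indicator plus covariate fixed
effects), with per-gene residual variances shrunk toward a common prior by
the standard empirical-Bayes moderated-t construction; the pairwise model
applies the same machinery to two groups only.  The resulting t-statistic
vectors are the molecular fingerprints consumed by spatial registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .data_model import CountAssay

D0_CAP = 500.0  # prior df cap; beyond this, shrinkage is effectively complete


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def log_cpm(counts: np.ndarray) -> np.ndarray:
    """Plain log2(CPM + 1) with no prior-count dialect."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log2(counts / safe[None, :] * 1e6 + 1.0)


@dataclass
class PseudobulkMatrix:
    """Summed counts per (group, sample) with a log2(CPM+1) view."""

    counts: np.ndarray
    gene_ids: np.ndarray
    meta: pd.DataFrame  # columns: group, sample, donor, n_obs

    @property
    def logexpr(self) -> np.ndarray:
        return log_cpm(self.counts)

    @property
    def groups(self) -> list:
        return list(pd.unique(self.meta["group"]))

    def subset_columns(self, mask) -> "PseudobulkMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return PseudobulkMatrix(self.counts[:, idx], self.gene_ids, self.meta.iloc[idx])


def concat_assays(assays: list) -> CountAssay:
    """Stack assays over observations on the shared (intersected) gene set."""
    common = set(assays[0].gene_ids)
    for a in assays[1:]:
        common &= set(a.gene_ids)
    if not common:
        raise ValueError("assays share no genes")
    genes = [g for g in assays[0].gene_ids if g in common]
    parts = [a.subset_genes(np.array(genes, dtype=object)) for a in assays]
    counts = sp.hstack([sp.csr_matrix(p.counts) for p in parts]).tocsr()
    obs_ids = np.concatenate([p.obs_ids for p in parts])
    obs_meta = pd.concat([p.obs_meta for p in parts])
    return CountAssay(counts, np.array(genes, dtype=object), obs_ids,
                      parts[0].gene_meta, obs_meta)


def pseudobulk(observations: CountAssay, group_key: str, sample_key: str,
               min_obs: int = 10, filter_cpm: float | None = 1.0) -> tuple[PseudobulkMatrix, pd.DataFrame]:
    """Sum counts over observations within each (group, sample) pair.

    Columns with fewer than ``min_obs`` member observations are dropped
    and reported.  Genes failing the expression prefilter (CPM >=
    ``filter_cpm`` in at least as many columns as the smallest group has;
    disabled with None) are removed before modeling.  Returns the matrix
    and a report of dropped columns.
    """
    meta = observations.obs_meta
    for key in (group_key, sample_key):
        if key not in meta:
            raise KeyError(f"obs_meta lacks '{key}'")
    counts = observations.counts
    dense = counts if not sp.issparse(counts) else counts
    cols, col_meta, dropped = [], [], []
    grouping = meta.groupby([group_key, sample_key], sort=True, observed=True)
    for (g, s), sub in grouping:
        idx = np.flatnonzero(meta.index.isin(sub.index))
        n = len(idx)
        summed = np.asarray(dense[:, idx].sum(axis=1)).ravel()
        donor = str(sub["donor"].iloc[0]) if "donor" in sub else str(s)
        if n < min_obs:
            dropped.append({"group": g, "sample": s, "n_obs": n})
            continue
        cols.append(summed)
        col_meta.append({"group": g, "sample": s, "donor": donor, "n_obs": n})
    if not col_meta:
        raise ValueError("no (group, sample) column met min_obs")
    mat = np.column_stack(cols)
    meta_df = pd.DataFrame(col_meta)
    meta_df.index = pd.Index(
        [f"{r.group}|{r.sample}" for r in meta_df.itertuples()], name="column"
    )
    if meta_df["group"].nunique() < 2:
        raise ValueError("fewer than 2 groups survive pseudobulking")
    pb = PseudobulkMatrix(mat, observations.gene_ids.copy(), meta_df)
    if filter_cpm is not None:
        cpm = pb.counts / np.where(pb.counts.sum(0) > 0, pb.counts.sum(0), 1)[None, :] * 1e6
        min_group = int(meta_df.groupby("group").size().min())
        keep = (cpm >= filter_cpm).sum(axis=1) >= min_group
        pb = PseudobulkMatrix(pb.counts[keep], pb.gene_ids[keep], pb.meta)
    report = pd.DataFrame(dropped, columns=["group", "sample", "n_obs"])
    return pb, report


# ----------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ----------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if -dif / y < 1e-10:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Moment-match a scaled inverse-chi-square prior on residual variances.

    Fits prior df d0 and prior variance s0^2 to the distribution of
    log(s^2) (digamma/trigamma moment equations), then returns the
    posterior variances (d0 * s0^2 + df * s^2) / (d0 + df).  d0 is capped
    at 500, where shrinkage is numerically complete.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 1e-300
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2))
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(evar), D0_CAP)
    s0_2 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, float(d0), s0_2


@dataclass
class DEStats:
    """Per-gene, per-group (or group-pair) DE statistics."""

    table: pd.DataFrame  # gene_id, group, logFC, t, p, fdr
    df_residual: float
    prior_df: float
    prior_var: float
    model: str = "enrichment"

    def for_group(self, group) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def t_matrix(self) -> pd.DataFrame:
        """Genes x groups matrix of t-statistics."""
        return self.table.pivot(index="gene_id", columns="group", values="t")

    def logfc_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="gene_id", columns="group", values="logFC")


def _design_with_covariates(indicator: np.ndarray, meta: pd.DataFrame,
                            covariates: list) -> np.ndarray:
    cols = [np.ones(len(indicator)), indicator.astype(float)]
    for cov in covariates:
        values = meta[cov].astype(str)
        levels = pd.unique(values)
        for lev in levels[1:]:  # drop first level
            cols.append((values == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"singular design: covariates {covariates} are collinear with the group indicator"
        )
    return X


def _fit_indicator_model(Y: np.ndarray, X: np.ndarray,
                         prior_df: float | None) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float]:
    """Shared-design least squares for all genes + variance moderation."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"not enough columns ({n}) for design with {p} parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv          # genes x p
    resid = Y - B @ X.T
    df = n - p
    s2 = (resid ** 2).sum(axis=1) / df
    v_bb = XtX_inv[1, 1]
    if prior_df is not None and prior_df == 0:
        post, d0, s0_2 = s2, 0.0, float("nan")
    else:
        post, d0, s0_2 = squeeze_variances(s2, df)
        if prior_df is not None:
            # fixed prior df with the moment-matched prior variance
            d0 = float(prior_df)
            post = (d0 * s0_2 + df * s2) / (d0 + df)
    beta = B[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(post * v_bb)
    t[~np.isfinite(t)] = 0.0
    pvals = 2.0 * t_dist.sf(np.abs(t), df + d0)
    return beta, t, pvals, df, d0, s0_2


def enrichment_model(pb: PseudobulkMatrix, covariates: list = ("donor",),
                     prior_df: float | None = None) -> DEStats:
    """One-vs-rest moderated-t enrichment statistics for every group.

    For each group the log-expression is regressed on a membership
    indicator plus covariate fixed effects; the indicator coefficient is
    the log2 fold-change of the group over the rest.  ``prior_df=0``
    disables moderation (ordinary per-gene OLS t).
    """
    covariates = [c for c in covariates if c in pb.meta.columns]
    Y = pb.logexpr
    groups = pb.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    d0_last = s0_last = df_last = 0.0
    for g in groups:
        ind = (pb.meta["group"] == g).to_numpy()
        X = _design_with_covariates(ind, pb.meta, covariates)
        beta, t, p, df, d0, s0_2 = _fit_indicator_model(Y, X, prior_df)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": pb.gene_ids,
                    "group": g,
                    "logFC": beta,
                    "t": t,
                    "p": p,
                    "fdr": bh_adjust(p),
                }
            )
        )
        d0_last, s0_last, df_last = d0, s0_2, df
    return DEStats(pd.concat(frames, ignore_index=True), df_last, d0_last, s0_last,
                   "enrichment")


def pairwise_model(pb: PseudobulkMatrix, group_a, group_b,
                   covariates: list = ("donor",), prior_df: float | None = None) -> DEStats:
    """Moderated-t contrast of two groups; logFC = mean(a) - mean(b)."""
    mask = pb.meta["group"].isin([group_a, group_b]).to_numpy()
    if not (pb.meta["group"] == group_a).any() or not (pb.meta["group"] == group_b).any():
        raise ValueError("both groups must be present")
    sub = pb.subset_columns(mask)
    covariates = [c for c in covariates if c in sub.meta.columns]
    ind = (sub.meta["group"] == group_a).to_numpy()
    X = _design_with_covariates(ind, sub.meta, covariates)
    beta, t, p, df, d0, s0_2 = _fit_indicator_model(sub.logexpr, X, prior_df)
    tab = pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "group": f"{group_a}_vs_{group_b}",
            "logFC": beta,
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
        }
    )
    return DEStats(tab, df, d0, s0_2, "pairwise")


def significant_genes(stats: DEStats, lfc_cut: float = 1.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Flag genes with fdr < alpha AND |logFC| > lfc_cut (both strict)."""
    tab = stats.table.copy()
    tab["significant"] = (tab["fdr"] < alpha) & (tab["logFC"].abs() > lfc_cut)
    return tab


def top_markers(stats: DEStats, n: int = 50, lfc_cut: float = 1.5,
                alpha: float = 0.05, require_significant: bool = True) -> dict:
    """Top ``n`` genes per group ranked by t descending.

    By default only genes passing the significance rule are eligible; if a
    group has fewer than ``n`` such genes its full eligible ranking is
    returned with a warning.
    """
    tab = significant_genes(stats, lfc_cut, alpha)
    out = {}
    for g, sub in tab.groupby("group", sort=False):
        eligible = sub[sub["significant"]] if require_significant else sub
        eligible = eligible.sort_values(["t", "gene_id"], ascending=[False, True], kind="stable")
        if len(eligible) < n:
            warnings.warn(f"group {g}: only {len(eligible)} eligible genes (< {n})")
        out[g] = eligible.head(n).reset_index(drop=True)
    return out
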