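"""Within-donor comparison of two regions' pseudobulk profiles.

The two regions' pseudobulk matrices are combined on their shared genes
with Tissue / Donor / Layer metadata and a derived Layer_Tissue factor.
Per gene, a linear mixed model with Layer_Tissue fixed effects and a donor
random intercept is fitted by REML (variance ratio profiled by
golden-section search on the log scale); the contrast between two
Layer_Tissue levels yields a Wald z and p-value.  A gene counts as a DEG
when |z| > 1.645 and |log2 FC| > 1.5 (both strict), and DEG counts over
all (region-A domain, region-B domain) pairs form a matrix scaled per
region-A row.  Enrichment log-fold-changes of matched domains across the
regions are classified as A-enriched / B-enriched / both by a logFC
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .pseudobulk import DEStats, PseudobulkMatrix, log_cpm


@dataclass
class CombinedPseudobulk:
    """Two regions' pseudobulks on shared genes with a Layer_Tissue factor."""

    counts: np.ndarray
    gene_ids: np.ndarray
    meta: pd.DataFrame  # Tissue, Donor, Layer, Layer_Tissue

    @property
    def logexpr(self) -> np.ndarray:
        return log_cpm(self.counts)

    def levels(self) -> list:
        return list(pd.unique(self.meta["Layer_Tissue"]))


def combine_pseudobulks(pb_A: PseudobulkMatrix, pb_B: PseudobulkMatrix,
                        tissue_a: str = "A", tissue_b: str = "B") -> CombinedPseudobulk:
    """Merge two region pseudobulks on the gene intersection.

    Library normalization is recomputed on the combined matrix.  Donors
    must be shared between the regions, otherwise the donor random effect
    is undefined.
    """
    shared = [g for g in pb_A.gene_ids if g in set(pb_B.gene_ids)]
    if not shared:
        raise ValueError("the two pseudobulks share no genes")
    pos_a = {g: i for i, g in enumerate(pb_A.gene_ids)}
    pos_b = {g: i for i, g in enumerate(pb_B.gene_ids)}
    counts = np.concatenate(
        [
            pb_A.counts[[pos_a[g] for g in shared], :],
            pb_B.counts[[pos_b[g] for g in shared], :],
        ],
        axis=1,
    )
    meta = pd.concat(
        [
            pd.DataFrame(
                {
                    "Tissue": tissue,
                    "Donor": pb.meta["donor"].to_numpy(),
                    "Layer": pb.meta["group"].to_numpy(),
                }
            )
            for pb, tissue in ((pb_A, tissue_a), (pb_B, tissue_b))
        ],
        ignore_index=True,
    )
    meta["Layer_Tissue"] = meta["Layer"].astype(str) + "_" + meta["Tissue"].astype(str)
    donors_a = set(meta.loc[meta["Tissue"] == tissue_a, "Donor"])
    donors_b = set(meta.loc[meta["Tissue"] == tissue_b, "Donor"])
    if not donors_a & donors_b:
        raise ValueError("no shared donors between regions; the donor random effect is undefined")
    return CombinedPseudobulk(counts, np.array(shared, dtype=object), meta)


# ----------------------------------------------------------------------
# REML random-intercept contrasts
# ----------------------------------------------------------------------

def _reml_criterion(lam, d, Yt_col, Xt, n, p):
    w = 1.0 / (1.0 + lam * d)
    XtWX = (Xt * w[:, None]).T @ Xt
    XtWy = (Xt * w[:, None]).T @ Yt_col
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    r = Yt_col - Xt @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        rss = 1e-300
    sign, logdet = np.linalg.slogdet(XtWX)
    crit = -np.sum(np.log(w)) + logdet + (n - p) * np.log(rss)
    return crit, beta, (XtWX, rss)


def mixed_model_contrast(cpb: CombinedPseudobulk, level_a: str, level_b: str,
                         tol: float = 1e-8, log_lambda_range=(-8.0, 8.0)) -> pd.DataFrame:
    """Per-gene REML contrast between two Layer_Tissue levels.

    The variance ratio lambda = var(donor) / var(residual) is profiled by
    golden-section search on log10(lambda); the contrast is the difference
    of the two level means with Wald inference on the normal reference.
    Genes where the search degenerates fall back to lambda = 0 (ordinary
    least squares) and are flagged.  Returns gene_id, logFC, z, p,
    lambda_ratio, converged.
    """
    levels = cpb.levels()
    for lev in (level_a, level_b):
        if lev not in levels:
            raise ValueError(f"Layer_Tissue level {lev!r} not present")
    Y = cpb.logexpr
    lt = cpb.meta["Layer_Tissue"].astype(str).to_numpy()
    X = np.column_stack([(lt == lev).astype(float) for lev in levels])  # cell-means coding
    donors = cpb.meta["Donor"].astype(str).to_numpy()
    donor_levels = pd.unique(donors)
    Z = np.column_stack([(donors == d).astype(float) for d in donor_levels])
    n, p = X.shape

    # shared eigenbasis of Z Z^T diagonalizes the covariance for every lambda
    d_eig, U = np.linalg.eigh(Z @ Z.T)
    Xt = U.T @ X
    Yt = Y @ U  # genes x n

    c = np.zeros(p)
    c[levels.index(level_a)] = 1.0
    c[levels.index(level_b)] = -1.0

    phi = (np.sqrt(5.0) - 1.0) / 2.0
    lo0, hi0 = log_lambda_range
    out = []
    for gi in range(Y.shape[0]):
        y = Yt[gi]
        # golden-section on log10(lambda), including the lambda ~ 0 boundary
        lo, hi = lo0, hi0
        x1 = hi - phi * (hi - lo)
        x2 = lo + phi * (hi - lo)
        f1, _, _ = _reml_criterion(10.0 ** x1, d_eig, y, Xt, n, p)
        f2, _, _ = _reml_criterion(10.0 ** x2, d_eig, y, Xt, n, p)
        while hi - lo > tol:
            if f1 <= f2:
                hi, x2, f2 = x2, x1, f1
                x1 = hi - phi * (hi - lo)
                f1, _, _ = _reml_criterion(10.0 ** x1, d_eig, y, Xt, n, p)
            else:
                lo, x1, f1 = x1, x2, f2
                x2 = lo + phi * (hi - lo)
                f2, _, _ = _reml_criterion(10.0 ** x2, d_eig, y, Xt, n, p)
        lam = 10.0 ** ((lo + hi) / 2.0)
        # accept the boundary lambda -> 0 when it is at least as good
        crit_zero, beta0, aux0 = _reml_criterion(0.0, d_eig, y, Xt, n, p)
        crit_opt, beta, aux = _reml_criterion(lam, d_eig, y, Xt, n, p)
        converged = np.isfinite(crit_opt)
        if not converged or crit_zero <= crit_opt:
            lam, beta, aux, crit_opt = 0.0, beta0, aux0, crit_zero
            converged = np.isfinite(crit_zero)
        if beta is None:
            out.append((cpb.gene_ids[gi], np.nan, np.nan, np.nan, 0.0, False))
            continue
        XtWX, rss = aux
        sigma2 = rss / (n - p)
        var_c = sigma2 * float(c @ np.linalg.solve(XtWX, c))
        est = float(c @ beta)
        z = est / np.sqrt(var_c) if var_c > 0 else 0.0
        pval = 2.0 * norm.sf(abs(z))
        out.append((cpb.gene_ids[gi], est, z, pval, lam, converged))
    return pd.DataFrame(
        out, columns=["gene_id", "logFC", "z", "p", "lambda_ratio", "converged"]
    )


def count_degs(contrast_results: pd.DataFrame, z_cut: float = 1.645,
               lfc_cut: float = 1.5) -> int:
    """Count genes with |z| > z_cut and |logFC| > lfc_cut (both strict)."""
    tab = contrast_results
    return int(((tab["z"].abs() > z_cut) & (tab["logFC"].abs() > lfc_cut)).sum())


def deg_count_matrix(cpb: CombinedPseudobulk, domains_a: list, domains_b: list,
                     tissue_a: str = "A", tissue_b: str = "B",
                     z_cut: float = 1.645, lfc_cut: float = 1.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DEG counts for every (A-domain, B-domain) pair, raw and row-scaled.

    Each scaled row divides by that A-domain's total DEGs over all its
    comparisons (rows with zero total stay zero).
    """
    raw = pd.DataFrame(0, index=list(domains_a), columns=list(domains_b), dtype=int)
    for da in domains_a:
        for db in domains_b:
            res = mixed_model_contrast(cpb, f"{da}_{tissue_a}", f"{db}_{tissue_b}")
            raw.loc[da, db] = count_degs(res, z_cut, lfc_cut)
    totals = raw.sum(axis=1)
    scaled = raw.astype(float).div(totals.where(totals > 0, 1), axis=0)
    scaled[totals == 0] = 0.0
    return raw, scaled


def logfc_concordance(stats_A: DEStats, stats_B: DEStats, group_a, group_b,
                      enrich_cut: float = 1.25) -> tuple[pd.DataFrame, float]:
    """Classify genes by region-enrichment of a matched domain pair.

    Over the shared genes, a gene is A-enriched when its enrichment logFC
    in region A exceeds ``enrich_cut`` while region B's does not,
    B-enriched symmetrically, 'both' when both exceed, else 'neither'.
    Also returns the Pearson correlation of the two logFC vectors over all
    shared genes.
    """
    a = stats_A.for_group(group_a).set_index("gene_id")["logFC"]
    b = stats_B.for_group(group_b).set_index("gene_id")["logFC"]
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    a, b = a.loc[shared], b.loc[shared]
    cat = np.where(
        (a > enrich_cut) & (b > enrich_cut), "both",
        np.where(a > enrich_cut, "A_enriched",
                 np.where(b > enrich_cut, "B_enriched", "neither")),
    )
    tab = pd.DataFrame(
        {"gene_id": shared, "logFC_A": a.to_numpy(), "logFC_B": b.to_numpy(), "category": cat}
    )
    r = float(pearsonr(a.to_numpy(), b.to_numpy())[0])
    return tab, r
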