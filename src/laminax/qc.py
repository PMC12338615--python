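"""Spot / nucleus quality control and feature selection.

SRT spots get the hard filter (out-of-tissue, all-zero, < 20 detected
genes, < 20 total UMIs, 100% mitochondrial); MAD-based outlier flags are
computed for reporting only.  snRNA-seq droplets are filtered by a
barcode-rank knee threshold, then nuclei by 3-MAD outlier rules.  Feature
selection uses Poisson deviance under a constant-proportion null, and the
same null yields Pearson residuals for PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import UnivariateSpline

from .data_model import CountAssay, SpatialSample

MAD_CONSISTENCY = 1.4826  # makes the MAD estimate sigma for normal data


@dataclass
class QCMetrics:
    """Per-observation totals, detected-gene counts and mito percentage."""

    sum: np.ndarray
    detected: np.ndarray
    mito_pct: np.ndarray
    obs_ids: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sum": self.sum, "detected": self.detected, "mito_pct": self.mito_pct},
            index=pd.Index(self.obs_ids, name="obs_id"),
        )


def compute_qc(assay: CountAssay) -> QCMetrics:
    """Library size, detected genes and mitochondrial rate per observation."""
    if "mito" not in assay.gene_meta:
        if "symbol" in assay.gene_meta:
            # standard convention: human mitochondrial genes are MT- prefixed
            assay.gene_meta["mito"] = (
                assay.gene_meta["symbol"].astype(str).str.upper().str.startswith("MT-")
            )
        else:
            raise ValueError("gene_meta must carry a 'mito' flag or 'symbol' column")
    totals = assay.obs_totals().astype(float)
    counts = assay.counts
    if sp.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=0)).ravel()
        mito_sum = np.asarray(
            counts[assay.gene_meta["mito"].to_numpy(bool), :].sum(axis=0)
        ).ravel()
    else:
        detected = (counts > 0).sum(axis=0)
        mito_sum = counts[assay.gene_meta["mito"].to_numpy(bool), :].sum(axis=0)
    if not assay.gene_meta["mito"].any():
        warnings.warn("no mito-flagged genes; mito_pct is all zero")
    with np.errstate(invalid="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_sum / np.where(totals > 0, totals, 1), 0.0)
    return QCMetrics(totals, detected.astype(int), mito_pct, assay.obs_ids)


def mad_outlier(values, nmads: float = 3.0, side: str = "both",
                log_transform: bool = False) -> np.ndarray:
    """Flag values beyond ``median +/- nmads * MAD`` on the chosen side.

    The MAD carries the 1.4826 normal-consistency constant.  A zero MAD is
    degenerate: nothing is flagged and a warning is emitted.
    """
    if side not in ("lower", "higher", "both"):
        raise ValueError("side must be lower, higher or both")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if log_transform:
        v = np.log1p(v)
    med = np.median(v)
    mad = MAD_CONSISTENCY * np.median(np.abs(v - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged")
        return np.zeros(v.shape, dtype=bool)
    lo = v < med - nmads * mad
    hi = v > med + nmads * mad
    return {"lower": lo, "higher": hi, "both": lo | hi}[side]


def filter_spots(sample: SpatialSample, min_detected: int = 20, min_sum: int = 20,
                 drop_mito100: bool = True) -> tuple[SpatialSample, pd.Series]:
    """Apply the hard spot filter and drop genes left with zero counts.

    A spot is removed when it is outside the tissue, has all-zero counts,
    fewer than ``min_detected`` detected genes, fewer than ``min_sum``
    total UMIs (both strict: a spot at exactly the threshold is kept), or
    a 100% mitochondrial rate.  Returns the filtered sample and a removal
    histogram keyed by reason (a spot counts once, under the first reason
    that applies in the order above).
    """
    qc = compute_qc(sample.assay)
    reasons = pd.Series(0, index=["out_of_tissue", "all_zero", "low_detected", "low_sum", "mito_100"])
    keep = np.ones(sample.n_spots, dtype=bool)
    checks = [
        ("out_of_tissue", ~sample.in_tissue),
        ("all_zero", qc.sum == 0),
        ("low_detected", qc.detected < min_detected),
        ("low_sum", qc.sum < min_sum),
        ("mito_100", (qc.mito_pct >= 100.0) if drop_mito100 else np.zeros(sample.n_spots, bool)),
    ]
    for name, bad in checks:
        newly = bad & keep
        reasons[name] = int(newly.sum())
        keep &= ~bad
    if not keep.any():
        raise ValueError(f"all spots removed; reasons: {reasons.to_dict()}")
    out = sample.subset(keep)
    gene_tot = np.asarray(out.assay.counts.sum(axis=1)).ravel()
    out = out.subset_genes(gene_tot > 0)
    return out, reasons


def filter_nuclei(assay: CountAssay, nmads: float = 3.0,
                  log_metrics: bool = True) -> tuple[CountAssay, pd.Series]:
    """MAD-based nucleus filter: low sum, low detected, high mito rate.

    Sum and detected are log1p-transformed before the MAD rule by default;
    the mito percentage is used raw.  All-zero nuclei and genes with zero
    total count afterwards are removed as well.
    """
    qc = compute_qc(assay)
    low_sum = mad_outlier(qc.sum, nmads, "lower", log_transform=log_metrics)
    low_det = mad_outlier(qc.detected, nmads, "lower", log_transform=log_metrics)
    hi_mito = mad_outlier(qc.mito_pct, nmads, "higher", log_transform=False)
    all_zero = qc.sum == 0
    reasons = pd.Series(
        {
            "all_zero": int(all_zero.sum()),
            "low_sum": int((low_sum & ~all_zero).sum()),
            "low_detected": int((low_det & ~all_zero & ~low_sum).sum()),
            "high_mito": int((hi_mito & ~all_zero & ~low_sum & ~low_det).sum()),
        }
    )
    keep = ~(all_zero | low_sum | low_det | hi_mito)
    if not keep.any():
        raise ValueError("all nuclei removed")
    out = assay.subset_obs(keep)
    gene_tot = np.asarray(out.counts.sum(axis=1)).ravel()
    return out.subset_genes(gene_tot > 0), reasons


# ----------------------------------------------------------------------
# Barcode-rank knee detection (droplet filter)
# ----------------------------------------------------------------------

def knee_threshold(total_counts, spline_smoothing: float | None = None) -> tuple[float, float]:
    """Locate knee and cliff of the log-log barcode-rank curve.

    Barcodes are ranked by total count with ties collapsed to a single
    point at their average rank.  A smoothing spline of log10(total) on
    log10(rank) gives first and second derivatives; the cliff is the point
    of steepest descent and the knee the point of minimum signed curvature
    at ranks at or below the cliff.  Returns (knee, cliff) on the count
    scale; barcodes with total below the knee are droppable.
    """
    totals = np.asarray(total_counts, dtype=float)
    totals = totals[totals > 0]
    if totals.size < 100:
        raise ValueError("need at least 100 barcodes with nonzero totals")
    order = np.sort(totals)[::-1]
    uniq, first_idx, counts = np.unique(-order, return_index=True, return_counts=True)
    uniq = -uniq  # descending unique totals
    avg_rank = first_idx + (counts + 1) / 2.0  # average 1-based rank of the tie group
    x = np.log10(avg_rank)
    y = np.log10(uniq)
    if uniq.size < 10 or np.ptp(y) < 1e-8:
        raise ValueError("barcode-rank curve is flat; no knee")
    s = spline_smoothing if spline_smoothing is not None else uniq.size * 1e-3
    spl = UnivariateSpline(x, y, k=3, s=s)
    d1 = spl.derivative(1)(x)
    d2 = spl.derivative(2)(x)
    curvature = d2 / (1 + d1 ** 2) ** 1.5
    if curvature.min() > -1e-3:
        raise ValueError("no knee: curve has no concave transition")
    cliff_i = int(np.argmin(d1))
    knee_i = int(np.argmin(curvature[: cliff_i + 1]))
    return float(uniq[knee_i]), float(uniq[cliff_i])


# ----------------------------------------------------------------------
# Feature selection under the constant-proportion Poisson null
# ----------------------------------------------------------------------

def _null_means(assay: CountAssay) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Y = assay.dense().astype(float)
    n_j = Y.sum(axis=0)
    grand = n_j.sum()
    pi_g = Y.sum(axis=1) / grand if grand > 0 else np.zeros(Y.shape[0])
    mu = np.outer(pi_g, n_j)
    return Y, mu, n_j


def poisson_deviance_selection(assay: CountAssay, n_top: int = 2000) -> pd.DataFrame:
    """Rank genes by Poisson deviance against the constant-proportion null.

    The null expects mu_gj = n_j * pi_g with pi_g the gene's share of the
    grand total; D_g = 2 * sum_j [y log(y/mu) - (y - mu)] with 0*log(0)=0.
    Returns the top ``n_top`` genes (all genes, with a warning, if fewer).
    """
    Y, mu, _ = _null_means(assay)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = Y * np.log(Y / mu)
    term[~np.isfinite(term)] = 0.0  # y == 0 or mu == 0
    dev = 2.0 * (term - (Y - mu)).sum(axis=1)
    dev = np.maximum(dev, 0.0)  # guard tiny negative rounding
    if n_top > assay.n_genes:
        warnings.warn(f"n_top={n_top} exceeds gene count {assay.n_genes}; returning all")
        n_top = assay.n_genes
    order = np.argsort(-dev, kind="stable")[:n_top]
    return pd.DataFrame(
        {"gene_id": assay.gene_ids[order], "deviance": dev[order]}
    ).reset_index(drop=True)


def null_pearson_residuals(assay: CountAssay) -> np.ndarray:
    """Pearson residuals (y - mu) / sqrt(mu) under the same Poisson null.

    Entries with mu = 0 (all-zero gene or column) are set to zero.  The
    residual matrix is the input to PCA in the GLM-PCA approximation.
    """
    Y, mu, _ = _null_means(assay)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y - mu) / np.sqrt(mu)
    r[~np.isfinite(r)] = 0.0
    return r
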