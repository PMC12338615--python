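"""Gene-set enrichment and heritability-annotation construction.

External DEG signatures (e.g. disease-associated genes from bulk RNA-seq)
are intersected with the local enrichment results, split into up- and
down-regulated sets, and tested against each domain's or cell type's
marker set by a two-sided Fisher's exact test over the shared gene
universe, with BH correction across the test family.  Mouse signatures
pass through an ortholog map first.  For heritability analyses, each
group's most specifically expressed genes (top decile of normalized CPM)
are expanded by a window on either side and written as BED intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pseudobulk import PseudobulkMatrix, DEStats, bh_adjust


@dataclass
class GeneSetTest:
    """One 2x2 Fisher test of set membership against a signature."""

    table: np.ndarray  # [[both, set_a_only], [set_b_only, neither]]
    odds_ratio: float
    p: float
    universe_size: int


def fisher_exact_2x2(a: int, b: int, c: int, d: int, tol: float = 1e-7) -> tuple[float, float]:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability is at most the observed table's
    (with relative tolerance ``tol`` on the comparison).  Returns
    (sample odds ratio, p).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(probs[probs <= p_obs * (1 + tol)].sum())
    p = min(1.0, p)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return odds, p


def fisher_test(set_a, set_b, universe) -> GeneSetTest:
    """Fisher's exact test of overlap between two gene sets in a universe."""
    uni = set(universe)
    sa = set(set_a) & uni
    sb = set(set_b) & uni
    if not sa or not sb:
        raise ValueError("degenerate margin: an input set is empty within the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    odds, p = fisher_exact_2x2(a, b, c, d)
    return GeneSetTest(np.array([[a, b], [c, d]]), odds, p, len(uni))


def build_signature_sets(external_table: pd.DataFrame, local_genes,
                         alpha: float = 0.1) -> dict:
    """Split an external DEG table into up / down / background sets.

    The universe is the overlap of the table's genes with the local
    results' genes.  Up = adjusted p < alpha and logFC > 0; down =
    adjusted p < alpha and logFC < 0 (both strict); background = the
    remaining universe genes.
    """
    tab = external_table.rename(columns=str.lower)
    for col in ("gene", "logfc", "adj_p"):
        if col not in tab:
            raise KeyError(f"external table lacks column '{col}'")
    tab = tab[tab["gene"].isin(set(local_genes))]
    if tab.empty:
        raise ValueError("no overlap between external table and local genes")
    sig = tab["adj_p"] < alpha
    up = set(tab.loc[sig & (tab["logfc"] > 0), "gene"])
    down = set(tab.loc[sig & (tab["logfc"] < 0), "gene"])
    universe = set(tab["gene"])
    return {"up": up, "down": down, "background": universe - up - down, "universe": universe}


def build_domain_sets(local_stats: DEStats, alpha: float = 0.05,
                      lfc: float = 1.0) -> dict:
    """Per-domain marker sets: fdr < alpha and logFC > lfc (strict).

    Domains with no qualifying gene get an empty set (tests on them are
    skipped downstream).
    """
    out = {}
    for g, sub in local_stats.table.groupby("group", sort=False):
        qual = sub[(sub["fdr"] < alpha) & (sub["logFC"] > lfc)]
        out[g] = set(qual["gene_id"])
    return out


def signature_enrichment(local_stats: DEStats, external_table: pd.DataFrame,
                         signature_alpha: float = 0.1, domain_alpha: float = 0.05,
                         domain_lfc: float = 1.0) -> pd.DataFrame:
    """Fisher enrichment of up/down signature sets in every domain set.

    Returns one row per (domain, direction) with the 2x2 counts, odds
    ratio, p and BH fdr across the whole family; empty domain sets are
    recorded as skipped.
    """
    local_genes = pd.unique(local_stats.table["gene_id"])
    sigs = build_signature_sets(external_table, local_genes, signature_alpha)
    domains = build_domain_sets(local_stats, domain_alpha, domain_lfc)
    universe = sigs["universe"]
    rows = []
    for domain, dset in domains.items():
        dset_u = dset & universe
        for direction in ("up", "down"):
            s = sigs[direction]
            if not dset_u or not s:
                rows.append({"domain": domain, "direction": direction, "skipped": True,
                             "overlap": 0, "odds_ratio": np.nan, "p": np.nan})
                continue
            res = fisher_test(s, dset_u, universe)
            rows.append(
                {
                    "domain": domain,
                    "direction": direction,
                    "skipped": False,
                    "overlap": int(res.table[0, 0]),
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                }
            )
    tab = pd.DataFrame(rows)
    ok = ~tab["skipped"]
    tab["fdr"] = np.nan
    tab.loc[ok, "fdr"] = bh_adjust(tab.loc[ok, "p"].to_numpy())
    return tab


def ortholog_map(genes, mapping_table: pd.DataFrame) -> tuple[list, dict]:
    """Map genes through a two-column (+ optional priority) ortholog table.

    One-to-one rows map directly; one-to-many conflicts resolve by the
    smallest value of a ``priority`` column when present, else all
    conflicting rows are dropped.  Returns the mapped targets (order of
    the input genes, unmapped skipped) and a drop report.
    """
    tab = mapping_table.rename(columns=str.lower)
    src_col, tgt_col = tab.columns[:2]
    report = {"unmatched": 0, "ambiguous_dropped": 0}
    chosen = {}
    for src, sub in tab.groupby(src_col, sort=False):
        if len(sub) == 1:
            chosen[src] = sub.iloc[0][tgt_col]
        elif "priority" in tab.columns:
            chosen[src] = sub.sort_values("priority", kind="stable").iloc[0][tgt_col]
        else:
            report["ambiguous_dropped"] += 1
    mapped = []
    for g in genes:
        if g in chosen:
            mapped.append(chosen[g])
        else:
            report["unmatched"] += 1
    return mapped, report


def specificity_annotation(pb: PseudobulkMatrix, gene_coords: pd.DataFrame,
                           top_frac: float = 0.10, window: int = 100_000,
                           min_obs: int = 50, min_cpm: float = 1.0,
                           score: str = "cpm") -> dict:
    """Per-group gene sets and BED windows for heritability annotation.

    Pseudobulk columns with fewer than ``min_obs`` member observations are
    dropped; genes must pass the CPM expression rule, have unique symbols,
    protein-coding biotype and known coordinates.  Per group the top
    ``top_frac`` of genes by normalized CPM (``score='cpm'``) or by the
    specificity ratio group CPM / total CPM (``score='ratio'``) are kept;
    their intervals, widened by ``window`` on each side and clipped at 0,
    are returned as 0-based half-open BED frames per group.
    """
    if score not in ("cpm", "ratio"):
        raise ValueError("score must be 'cpm' or 'ratio'")
    keep_cols = pb.meta["n_obs"].to_numpy() >= min_obs
    if not keep_cols.any():
        raise ValueError("no pseudobulk column meets min_obs")
    sub = pb.subset_columns(keep_cols)
    counts = sub.counts.astype(float)
    totals = counts.sum(axis=0)
    cpm = counts / np.where(totals > 0, totals, 1)[None, :] * 1e6
    min_group = int(sub.meta.groupby("group").size().min())
    expressed = (cpm >= min_cpm).sum(axis=1) >= min_group

    coords = gene_coords.set_index("gene_id") if "gene_id" in gene_coords else gene_coords
    info = coords.reindex(sub.gene_ids)
    has_coords = info["chrom"].notna().to_numpy()
    coding = (info["biotype"].astype(str) == "protein_coding").to_numpy()
    symbols = info["symbol"].astype(str) if "symbol" in info else pd.Series(
        sub.gene_ids, index=info.index
    )
    unique_symbol = ~symbols.duplicated(keep=False).to_numpy()
    keep = expressed & has_coords & coding & unique_symbol
    dropped = {
        "low_expression": int((~expressed).sum()),
        "missing_coords": int((expressed & ~has_coords).sum()),
        "non_coding": int((expressed & has_coords & ~coding).sum()),
        "duplicate_symbol": int((expressed & has_coords & coding & ~unique_symbol).sum()),
    }
    genes = sub.gene_ids[keep]
    cpm_k = cpm[keep]
    info_k = info.loc[genes]

    # mean CPM per group
    group_cpm = pd.DataFrame(
        {g: cpm_k[:, (sub.meta["group"] == g).to_numpy()].mean(axis=1) for g in sub.groups},
        index=genes,
    )
    beds, sets = {}, {}
    n_top = max(1, int(round(top_frac * len(genes))))
    for g in sub.groups:
        vals = group_cpm[g]
        if score == "ratio":
            denom = group_cpm.sum(axis=1)
            vals = vals / denom.where(denom > 0, 1)
        top = vals.sort_values(ascending=False, kind="stable").head(n_top).index
        sets[g] = list(top)
        bed = pd.DataFrame(
            {
                "chrom": info_k.loc[top, "chrom"].to_numpy(),
                "start": np.maximum(0, info_k.loc[top, "start"].to_numpy(dtype=int) - window),
                "end": info_k.loc[top, "end"].to_numpy(dtype=int) + window,
                "name": top.to_numpy(),
            }
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        beds[g] = bed
    return {"gene_sets": sets, "beds": beds, "dropped": dropped, "n_top": n_top}


def write_beds(beds: dict, out_dir) -> list:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for g, bed in beds.items():
        path = out / f"{str(g).replace('/', '_')}.bed"
        bed.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths
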