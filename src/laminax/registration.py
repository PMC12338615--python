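"""Spatial registration: correlating enrichment fingerprints across systems.

Two annotation systems (e.g. data-driven spatial domains vs manually
annotated layers, or cell types vs spatial domains) are compared by taking
each reference group's top ``top_n`` marker genes by enrichment t, pooling
them over reference groups, and computing the Pearson correlation of the
two systems' t-vectors over that marker union for every (reference group,
query group) combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudobulk import DEStats


@dataclass
class RegistrationMatrix:
    """Reference-groups x query-groups correlation of marker t-statistics."""

    corr: pd.DataFrame
    genes_used: list
    top_n: int
    direction: str = "reference->query"
    confident: pd.DataFrame | None = None

    def row_argmax(self) -> pd.Series:
        return self.corr.idxmax(axis=1)


def register(stats_ref: DEStats, stats_query: DEStats, top_n: int = 100) -> RegistrationMatrix:
    """Correlate two systems' enrichment t-statistics over top markers.

    The marker set is the union, over reference groups, of each group's
    ``top_n`` genes by t computed on the common-gene intersection.
    Correlations over a zero-variance t-vector are reported as missing
    (NaN), never as 0.
    """
    t_ref = stats_ref.t_matrix()
    t_query = stats_query.t_matrix()
    common = t_ref.index.intersection(t_query.index)
    if len(common) < top_n:
        raise ValueError(
            f"only {len(common)} genes shared between the two stats; need >= top_n={top_n}"
        )
    t_ref = t_ref.loc[common]
    t_query = t_query.loc[common]
    markers: set = set()
    for g in t_ref.columns:
        top = t_ref[g].sort_values(ascending=False, kind="stable").head(top_n)
        markers |= set(top.index)
    genes = sorted(markers)
    R = pd.DataFrame(index=t_ref.columns, columns=t_query.columns, dtype=float)
    A = t_ref.loc[genes]
    B = t_query.loc[genes]
    for r in R.index:
        a = A[r].to_numpy(dtype=float)
        for q in R.columns:
            b = B[q].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b) == 0:
                R.loc[r, q] = np.nan
            else:
                R.loc[r, q] = float(np.corrcoef(a, b)[0, 1])
    return RegistrationMatrix(R, genes, top_n)


def mark_confidence(reg: RegistrationMatrix, cutoff: float = 0.25) -> pd.DataFrame:
    """Boolean high-confidence mask: correlation >= cutoff (inclusive)."""
    conf = reg.corr >= cutoff
    reg.confident = conf
    return conf
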