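"""Shared containers and IO for paired SRT / snRNA-seq analysis.

The canonical in-memory orientation is genes x observations: rows of every
count matrix are genes, columns are spots or nuclei.  Readers transpose as
needed.  Observation/gene alignment is always by identifier with set
semantics; order never carries meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


def _check_unique(ids: np.ndarray, what: str) -> None:
    vals, counts = np.unique(ids.astype(str), return_counts=True)
    dups = vals[counts > 1]
    if dups.size:
        raise FormatError(f"duplicate {what}: {', '.join(map(str, dups[:5]))}")


@dataclass
class CountAssay:
    """A genes x observations count matrix with aligned metadata tables.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows (dense or scipy sparse).
    gene_ids, obs_ids
        Unique string identifiers for rows and columns.
    gene_meta, obs_meta
        Optional tables indexed by the respective identifiers.  Typical
        gene columns: ``symbol``, ``chrom``, ``start``, ``end``, ``biotype``,
        ``mito``.  Typical observation columns: ``donor``, ``sample``,
        group labels and numeric QC fields.
    """

    counts: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    obs_ids: np.ndarray
    gene_meta: pd.DataFrame = None
    obs_meta: pd.DataFrame = None

    def __post_init__(self):
        self.gene_ids = _as_str_array(self.gene_ids)
        self.obs_ids = _as_str_array(self.obs_ids)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.obs_ids, "observation ids")
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise FormatError("counts must be finite and non-negative")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        else:
            self.gene_meta = self.gene_meta.loc[list(self.gene_ids)]
        if self.obs_meta is None:
            self.obs_meta = pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id"))
        else:
            self.obs_meta = self.obs_meta.loc[list(self.obs_ids)]

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def dense(self) -> np.ndarray:
        c = self.counts
        return np.asarray(c.todense()) if sp.issparse(c) else np.asarray(c)

    def obs_totals(self) -> np.ndarray:
        """Total UMIs per observation."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_genes(self, mask_or_ids) -> "CountAssay":
        idx = self._index(mask_or_ids, self.gene_ids)
        return CountAssay(
            self.counts[idx, :],
            self.gene_ids[idx],
            self.obs_ids,
            self.gene_meta.iloc[idx],
            self.obs_meta,
        )

    def subset_obs(self, mask_or_ids) -> "CountAssay":
        idx = self._index(mask_or_ids, self.obs_ids)
        counts = self.counts.tocsc()[:, idx].tocsr() if sp.issparse(self.counts) else self.counts[:, idx]
        return CountAssay(
            counts, self.gene_ids, self.obs_ids[idx], self.gene_meta, self.obs_meta.iloc[idx]
        )

    @staticmethod
    def _index(mask_or_ids, ids: np.ndarray) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.shape != ids.shape:
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr.astype(int)
        pos = {g: i for i, g in enumerate(ids)}
        missing = [g for g in arr if g not in pos]
        if missing:
            raise KeyError(f"unknown ids: {missing[:5]}")
        return np.array([pos[g] for g in arr], dtype=int)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (observations as rows)."""
        import anndata as ad

        X = self.counts.T.tocsr() if sp.issparse(self.counts) else self.counts.T.copy()
        return ad.AnnData(X=X, obs=self.obs_meta.copy(), var=self.gene_meta.copy())


@dataclass
class SpatialSample:
    """One capture area: a :class:`CountAssay` plus spot geometry."""

    assay: CountAssay
    xy: np.ndarray
    in_tissue: np.ndarray
    sample_id: str = ""
    donor: str = ""
    domain: np.ndarray | None = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        n = self.assay.n_obs
        if self.xy.shape != (n, 2):
            raise FormatError(f"xy shape {self.xy.shape} != ({n}, 2)")
        if self.in_tissue.shape != (n,):
            raise FormatError("in_tissue length mismatch")
        if self.domain is not None:
            self.domain = _as_str_array(self.domain)
            if self.domain.shape != (n,):
                raise FormatError("domain length mismatch")

    @property
    def n_spots(self) -> int:
        return self.assay.n_obs

    def subset(self, mask_or_ids) -> "SpatialSample":
        idx = CountAssay._index(mask_or_ids, self.assay.obs_ids)
        return SpatialSample(
            self.assay.subset_obs(idx),
            self.xy[idx],
            self.in_tissue[idx],
            self.sample_id,
            self.donor,
            None if self.domain is None else self.domain[idx],
        )

    def subset_genes(self, mask_or_ids) -> "SpatialSample":
        return SpatialSample(
            self.assay.subset_genes(mask_or_ids),
            self.xy,
            self.in_tissue,
            self.sample_id,
            self.donor,
            self.domain,
        )


@dataclass
class LogNormMatrix:
    """Library-size normalized log2 expression (genes x observations).

    ``cp10k`` gives log2(count / column_total * 1e4 + 1); ``cpm`` gives
    log2(CPM + 1).  All-zero columns map to all-zero output columns.
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    obs_ids: np.ndarray
    normalization: str = "cp10k"

    def dense(self) -> np.ndarray:
        v = self.values
        return np.asarray(v.todense()) if sp.issparse(v) else np.asarray(v)


_NORM_SCALE = {"cp10k": 1e4, "cpm": 1e6}


def log_normalize(assay: CountAssay, mode: str = "cp10k") -> LogNormMatrix:
    """log2-transformed library-size-normalized expression."""
    if mode not in _NORM_SCALE:
        raise ValueError(f"mode must be one of {sorted(_NORM_SCALE)}")
    scale = _NORM_SCALE[mode]
    totals = assay.obs_totals().astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    if sp.issparse(assay.counts):
        m = assay.counts.tocsc().astype(float)
        # scale each column in place on the sparse data; zeros stay zero
        for j in range(m.shape[1]):
            sl = slice(m.indptr[j], m.indptr[j + 1])
            m.data[sl] = np.log2(m.data[sl] / safe[j] * scale + 1.0)
        values = m.tocsr()
    else:
        values = np.log2(assay.counts / safe[None, :] * scale + 1.0)
    return LogNormMatrix(values, assay.gene_ids, assay.obs_ids, mode)


# ----------------------------------------------------------------------
# 10x-dialect readers and writers
# ----------------------------------------------------------------------

def _read_table(path, **kw) -> pd.DataFrame:
    # pandas infers gzip from the .gz suffix
    return pd.read_csv(path, sep="\t", header=None, **kw)


def read_10x_mtx(matrix_path, features_path, barcodes_path) -> CountAssay:
    """Read a Matrix Market count matrix with 10x-style annotation tables.

    Features (rows of the matrix) become genes; the features file may carry
    id, symbol and feature-type columns.  Gzipped or plain files are both
    accepted.
    """
    mat = mmread(str(matrix_path))
    mat = sp.csr_matrix(mat)
    feats = _read_table(features_path)
    bcs = _read_table(barcodes_path)
    if mat.shape[0] != len(feats) or mat.shape[1] != len(bcs):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but annotation tables "
            f"have {len(feats)} features and {len(bcs)} barcodes"
        )
    gene_ids = feats.iloc[:, 0].astype(str).to_numpy()
    gene_meta = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if feats.shape[1] > 1:
        gene_meta["symbol"] = feats.iloc[:, 1].astype(str).to_numpy()
    if feats.shape[1] > 2:
        gene_meta["feature_type"] = feats.iloc[:, 2].astype(str).to_numpy()
    obs_ids = bcs.iloc[:, 0].astype(str).to_numpy()
    return CountAssay(mat, gene_ids, obs_ids, gene_meta=gene_meta)


def write_10x_mtx(assay: CountAssay, out_dir) -> None:
    """Write ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` (plain text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = assay.counts if sp.issparse(assay.counts) else sp.csr_matrix(assay.counts)
    mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(mat))
    symbols = (
        assay.gene_meta["symbol"].astype(str).to_numpy()
        if "symbol" in assay.gene_meta
        else assay.gene_ids
    )
    pd.DataFrame({0: assay.gene_ids, 1: symbols, 2: "Gene Expression"}).to_csv(
        out / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({0: assay.obs_ids}).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )


_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def read_spot_positions(positions_path, assay: CountAssay, sample_id: str = "",
                        donor: str = "") -> SpatialSample:
    """Attach a Visium tissue-positions table to a count assay.

    Both the headered and headerless CSV dialects are accepted.  Spots are
    matched to assay barcodes by identifier; position rows whose barcode is
    absent from the assay are dropped (their number is reported in a
    warning).  Zero overlapping barcodes is an error.
    """
    head = pd.read_csv(positions_path, nrows=1, header=None)
    has_header = any("barcode" in str(v).lower() for v in head.iloc[0])
    tab = pd.read_csv(positions_path, header=0 if has_header else None)
    tab = tab.iloc[:, : len(_POSITION_COLS)]
    tab.columns = _POSITION_COLS[: tab.shape[1]]
    tab["barcode"] = tab["barcode"].astype(str)

    known = set(assay.obs_ids.astype(str))
    keep = tab["barcode"].isin(known)
    n_dropped = int((~keep).sum())
    tab = tab[keep]
    if tab.empty:
        raise FormatError("no overlapping barcodes between positions table and assay")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} position barcodes absent from the assay")
    tab = tab.drop_duplicates("barcode").set_index("barcode")
    # keep the assay's own barcode order so input file order carries no meaning
    present = set(tab.index)
    ordered = np.array([b for b in assay.obs_ids if b in present], dtype=object)
    sub = assay.subset_obs(ordered)
    tab = tab.loc[list(sub.obs_ids)]
    xy = tab[["pxl_col", "pxl_row"]].to_numpy(dtype=float)
    return SpatialSample(
        sub, xy, tab["in_tissue"].to_numpy(dtype=int).astype(bool), sample_id, donor
    )
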