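import numpy as np
import pandas as pd
import pytest

import laminax as lx


@pytest.fixture(scope="session")
def small_sim():
    """A small paired-region dataset shared by recovery tests."""
    cfg = lx.SimConfig(n_donors=4, n_genes=600, n_nuclei_per_donor=150,
                       markers_per_layer=10, seed=7)
    samples, nuclei, truth = lx.simulate_paired_regions(cfg)
    return cfg, samples, nuclei, truth


@pytest.fixture()
def toy_assay():
    """3 genes x 4 observations with one mito gene."""
    counts = np.array(
        [
            [5, 0, 1, 0],
            [0, 0, 2, 0],
            [15, 0, 3, 4],
        ]
    )
    gene_meta = pd.DataFrame(
        {"symbol": ["A", "B", "MT-1"], "mito": [False, False, True]},
        index=pd.Index(["gA", "gB", "gMT"], name="gene_id"),
    )
    return lx.CountAssay(
        counts, ["gA", "gB", "gMT"], ["s1", "s2", "s3", "s4"], gene_meta=gene_meta
    )


def make_spatial(counts, in_tissue=None, xy=None, mito=None, domain=None):
    counts = np.asarray(counts)
    G, n = counts.shape
    gene_ids = [f"g{i}" for i in range(G)]
    gene_meta = pd.DataFrame(
        {"mito": (mito if mito is not None else [False] * G)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    assay = lx.CountAssay(counts, gene_ids, [f"s{j}" for j in range(n)], gene_meta=gene_meta)
    xy = np.column_stack([np.arange(n), np.zeros(n)]) if xy is None else np.asarray(xy)
    in_tissue = np.ones(n, bool) if in_tissue is None else np.asarray(in_tissue, bool)
    return lx.SpatialSample(assay, xy, in_tissue, "toy", "d0", domain)
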