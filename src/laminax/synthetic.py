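"""Synthetic paired SRT + snRNA-seq data with known ground truth.

The generator emulates the study design that motivates the pipeline: two
cortical regions sampled from the same donors, where region A (an agranular
cortex) lacks the granular L4 band present in region B (a granular
neocortex), and where a rare spindle-neuron-like cell type is confined to
the deeper half of region A's L5 band.  Matched single-nucleus profiles per
donor carry layer-aligned cell types plus the rare type.  Counts are
negative binomial (gamma-Poisson) with per-gene base rates, band/type
marker multipliers, per-donor lognormal effects and per-observation library
sizes; a designated set of "technical" genes additionally scales with
library size so that factor analyses pick up a technical pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountAssay, SpatialSample

N_MITO = 13  # human mitochondrial protein-coding gene count
SPECIFIC_BASE_SCALE = 0.01  # off-target level of the highly specific programs


@dataclass
class SimConfig:
    """Parameters of the paired-region simulation.

    marker_lfc is the log2 effect of a marker gene in its home band or cell
    type; libsize_lognormal are (mu, sigma) of per-observation library
    sizes on the natural-log scale; nb_dispersion is the gamma-Poisson
    overdispersion phi with variance mu + phi * mu^2; donor_sd is the
    lognormal sigma of per-(gene, donor) effects.
    """

    n_donors: int = 10
    n_genes: int = 2000
    layers_A: tuple = ("L1", "L2", "L3", "L5", "L6a", "L6b", "WM")
    layers_B: tuple = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")
    spots_per_band: int = 20
    n_cols: int = 5
    markers_per_layer: int = 40
    marker_lfc: float = 2.0
    rare_type_prevalence: float = 0.05
    libsize_lognormal: tuple = (7.6, 0.35)
    nb_dispersion: float = 0.25
    donor_sd: float = 0.1
    technical_factor_genes: int = 50
    n_nuclei_per_donor: int = 300
    seed: int = 7

    def band_labels(self) -> list:
        seen = []
        for b in tuple(self.layers_A) + tuple(self.layers_B):
            if b not in seen:
                seen.append(b)
        return seen

    def program_labels(self) -> list:
        return self.band_labels() + ["deep_L5", "rare"]

    def validate(self) -> None:
        if len(self.layers_A) < 3 or len(self.layers_B) < 3:
            raise ValueError("each region needs at least 3 bands")
        if not (0 < self.rare_type_prevalence < 0.5):
            raise ValueError("rare_type_prevalence must lie in (0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.spots_per_band % self.n_cols:
            raise ValueError("spots_per_band must be a multiple of n_cols")
        n_band = self.markers_per_layer * len(self.band_labels())
        n_spec = 2 * min(self.markers_per_layer, 10)
        needed = N_MITO + n_band + n_spec + self.technical_factor_genes
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible config: {needed} structured genes exceed n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    spot_band: dict           # sample_id -> band label per spot
    deep_l5: dict             # sample_id -> bool per spot (deep half of L5)
    nucleus_type: np.ndarray  # true type per nucleus
    marker_sets: dict         # program label -> list of gene ids (disjoint)
    planted_rank: int
    technical_gene_ids: list = field(default_factory=list)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson counts with mean mu and variance mu + phi * mu**2."""
    lam = rng.gamma(1.0 / phi, phi * mu)
    return rng.poisson(lam)


def _gene_frame(cfg: SimConfig) -> tuple[np.ndarray, pd.DataFrame, dict, list]:
    gene_ids = np.array([f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    mito = np.zeros(cfg.n_genes, dtype=bool)
    mito[:N_MITO] = True
    symbols = np.array(
        [f"MT-{i}" if i < N_MITO else f"GENE{i:04d}" for i in range(cfg.n_genes)],
        dtype=object,
    )
    # marker sets are disjoint blocks after the mito genes; band programs
    # span markers_per_layer genes (laminar signatures are broad), while
    # the deep-L5 and rare programs are small sets of highly specific genes
    marker_sets, pos = {}, N_MITO
    for label in cfg.program_labels():
        n_set = min(cfg.markers_per_layer, 10) if label in ("deep_L5", "rare") else cfg.markers_per_layer
        marker_sets[label] = list(gene_ids[pos : pos + n_set])
        pos += n_set
    technical = list(gene_ids[pos : pos + cfg.technical_factor_genes])
    # simple genome layout for annotation-construction tests
    chrom = np.array([f"chr{(i % 22) + 1}" for i in range(cfg.n_genes)], dtype=object)
    start = 100_000 + 50_000 * (np.arange(cfg.n_genes) // 22)
    biotype = np.where(np.arange(cfg.n_genes) % 29 == 28, "lincRNA", "protein_coding")
    gene_meta = pd.DataFrame(
        {
            "symbol": symbols,
            "mito": mito,
            "chrom": chrom,
            "start": start,
            "end": start + 20_000,
            "biotype": biotype,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return gene_ids, gene_meta, marker_sets, technical


def simulate_paired_regions(cfg: SimConfig):
    """Simulate paired-region SRT samples, matched nuclei and ground truth.

    Returns
    -------
    samples : dict mapping region ("A" / "B") to a list of SpatialSample,
        one per donor.  Spot metadata carries donor, band (the true layer,
        usable as a spatial-domain label) and a deep-L5 flag.
    nuclei : CountAssay of all donors' nuclei with donor / sex / sort /
        cell_type metadata.
    truth : GroundTruth
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids, gene_meta, marker_sets, technical = _gene_frame(cfg)
    gidx = {g: i for i, g in enumerate(gene_ids)}

    base = rng.lognormal(0.0, 1.0, cfg.n_genes)
    base[:N_MITO] *= 8.0  # mitochondrial transcripts are abundant
    # the deep-L5 and rare programs are built from highly specific genes:
    # near-silent at baseline, strongly expressed in their home context
    # (in-target level boost^2 x typical, so the on/off ratio is
    # boost^2 / SPECIFIC_BASE_SCALE)
    specific_idx = [gidx[g] for g in marker_sets["deep_L5"] + marker_sets["rare"]]
    base[specific_idx] *= SPECIFIC_BASE_SCALE
    boost = 2.0 ** cfg.marker_lfc
    spec_on = boost ** 2 / SPECIFIC_BASE_SCALE
    donor_eff = rng.lognormal(0.0, cfg.donor_sd, (cfg.n_donors, cfg.n_genes))
    donors = [f"D{d:02d}" for d in range(cfg.n_donors)]
    sexes = {d: ("M" if i % 2 == 0 else "F") for i, d in enumerate(donors)}
    tech_idx = np.array([gidx[g] for g in technical], dtype=int)
    lib_mu, lib_sd = cfg.libsize_lognormal

    rows_per_band = cfg.spots_per_band // cfg.n_cols

    def _sample_counts(bands: list, region: str, donor_i: int):
        n_bands = len(bands)
        n_spots = cfg.spots_per_band * n_bands
        row = np.repeat(np.arange(rows_per_band * n_bands), cfg.n_cols)
        col = np.tile(np.arange(cfg.n_cols), rows_per_band * n_bands)
        band_of = np.array(bands, dtype=object)[row // rows_per_band]
        band_row = row % rows_per_band
        deep = (band_of == "L5") & (band_row >= rows_per_band // 2)

        mult = np.ones((cfg.n_genes, n_spots))
        for b in set(bands):
            in_b = band_of == b
            mi = [gidx[g] for g in marker_sets[b]]
            mult[np.ix_(mi, np.flatnonzero(in_b))] = boost
        di = [gidx[g] for g in marker_sets["deep_L5"]]
        mult[np.ix_(di, np.flatnonzero(deep))] = spec_on
        if region == "A":
            # rare-type cells sit only in the deep half of L5's band
            ri = [gidx[g] for g in marker_sets["rare"]]
            mult[np.ix_(ri, np.flatnonzero(deep))] = spec_on

        lib = rng.lognormal(lib_mu, lib_sd, n_spots)
        mult[tech_idx, :] *= (lib / np.exp(lib_mu))[None, :]
        rel = base[:, None] * donor_eff[donor_i][:, None] * mult
        mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
        counts = _nb_draw(rng, mu, cfg.nb_dispersion)
        xy = np.column_stack([col * 100.0, row * 100.0])
        return counts, xy, band_of, deep

    samples = {"A": [], "B": []}
    truth_band, truth_deep = {}, {}
    for region, bands in (("A", list(cfg.layers_A)), ("B", list(cfg.layers_B))):
        for donor_i, donor in enumerate(donors):
            sid = f"{region}_{donor}"
            counts, xy, band_of, deep = _sample_counts(bands, region, donor_i)
            obs_ids = np.array([f"{sid}_s{j:04d}" for j in range(counts.shape[1])], dtype=object)
            obs_meta = pd.DataFrame(
                {
                    "donor": donor,
                    "sample": sid,
                    "region": region,
                    "band": band_of,
                    "deep_l5": deep,
                },
                index=pd.Index(obs_ids, name="obs_id"),
            )
            assay = CountAssay(counts, gene_ids, obs_ids, gene_meta, obs_meta)
            samples[region].append(
                SpatialSample(assay, xy, np.ones(len(obs_ids), bool), sid, donor, band_of)
            )
            truth_band[sid] = band_of
            truth_deep[sid] = deep

    # ------------------------------------------------------------- nuclei
    types = list(cfg.layers_A) + ["L5_deep", "VEN"]
    n_common = len(types) - 1
    p_common = (1.0 - cfg.rare_type_prevalence) / n_common
    probs = np.array([p_common] * n_common + [cfg.rare_type_prevalence])
    all_counts, all_meta, all_types = [], [], []
    for donor_i, donor in enumerate(donors):
        n = cfg.n_nuclei_per_donor
        t_idx = rng.choice(len(types), size=n, p=probs)
        mult = np.ones((cfg.n_genes, n))
        for ti, t in enumerate(types):
            cols = np.flatnonzero(t_idx == ti)
            if not cols.size:
                continue
            if t == "VEN":
                mult[np.ix_([gidx[g] for g in marker_sets["rare"]], cols)] = spec_on
                mult[np.ix_([gidx[g] for g in marker_sets["deep_L5"]], cols)] = spec_on / 2.0
            elif t == "L5_deep":
                mult[np.ix_([gidx[g] for g in marker_sets["deep_L5"]], cols)] = spec_on
                mult[np.ix_([gidx[g] for g in marker_sets["L5"]], cols)] = boost / 2.0
            else:
                mult[np.ix_([gidx[g] for g in marker_sets[t]], cols)] = boost
        lib = rng.lognormal(lib_mu, lib_sd, n)
        mult[tech_idx, :] *= (lib / np.exp(lib_mu))[None, :]
        rel = base[:, None] * donor_eff[donor_i][:, None] * mult
        mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
        all_counts.append(_nb_draw(rng, mu, cfg.nb_dispersion))
        sort = np.where(rng.random(n) < 0.5, "PI", "PI_NeuN")
        all_meta.append(
            pd.DataFrame(
                {
                    "donor": donor,
                    "sex": sexes[donor],
                    "sort": sort,
                    "cell_type": np.array(types, dtype=object)[t_idx],
                }
            )
        )
        all_types.append(np.array(types, dtype=object)[t_idx])

    counts = np.concatenate(all_counts, axis=1)
    nuc_ids = np.array([f"n{j:05d}" for j in range(counts.shape[1])], dtype=object)
    obs_meta = pd.concat(all_meta, ignore_index=True)
    obs_meta.index = pd.Index(nuc_ids, name="obs_id")
    nuclei = CountAssay(counts, gene_ids, nuc_ids, gene_meta, obs_meta)

    truth = GroundTruth(
        spot_band=truth_band,
        deep_l5=truth_deep,
        nucleus_type=np.concatenate(all_types),
        marker_sets=marker_sets,
        planted_rank=len(cfg.program_labels()),
        technical_gene_ids=technical,
    )
    return samples, nuclei, truth


# ----------------------------------------------------------------------
# smFISH simulation
# ----------------------------------------------------------------------

SMFISH_ANCHOR = "PCP4"
SMFISH_TARGETS = ("POU3F1", "SULF2", "GABRQ")


def simulate_smfish(
    n_cells: int = 2000,
    expressor_fraction: float = 0.3,
    mu_off: float = 0.5,
    mu_on: float = 20.0,
    area_lognormal: tuple = (4.4, 0.3),
    anchor_band_geometry: tuple = (150.0, 350.0),
    seed: int = 1,
) -> pd.DataFrame:
    """Simulate a per-cell smFISH table with a banded anchor gene.

    Cells are scattered uniformly on a 500 x 500 um field.  The anchor gene
    (a layer-5 marker stand-in) is elevated only inside the horizontal band
    ``anchor_band_geometry`` (y-limits), with two positive expression
    levels so that a k=3 gate separates negative / medium / high.  Each
    target gene is expressed in a random ``expressor_fraction`` of cells as
    a two-component mixture N(mu_on, 3^2) vs N(mu_off, 0.5^2) (clipped at
    0).  Observed copy counts scale with relative cell area, and signal
    intensity is linear in the observed copies plus noise.

    Ground-truth columns are prefixed ``true_``.
    """
    if not mu_on > mu_off >= 0:
        raise ValueError("require mu_on > mu_off >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 500, n_cells)
    y = rng.uniform(0, 500, n_cells)
    area = rng.lognormal(*area_lognormal, n_cells)
    rel_area = area / np.median(area)
    y0, y1 = anchor_band_geometry
    in_band = (y >= y0) & (y <= y1)

    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "x": x,
            "y": y,
            "area": area,
            "true_in_band": in_band,
        }
    )

    def _observe(copies_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        copies = np.clip(copies_true, 0, None) * rel_area
        intensity = np.clip(2.0 * copies + rng.normal(0, 1.0, n_cells), 0, None)
        return copies, intensity

    # anchor: off outside the band; medium/high levels inside
    anchor_true = rng.normal(mu_off, 0.5, n_cells)
    hi = in_band & (rng.random(n_cells) < 0.5)
    med = in_band & ~hi
    anchor_true[med] = rng.normal(0.5 * mu_on, 2.0, med.sum())
    anchor_true[hi] = rng.normal(1.5 * mu_on, 4.0, hi.sum())
    df[f"{SMFISH_ANCHOR}_copies"], df[f"{SMFISH_ANCHOR}_intensity"] = _observe(anchor_true)

    for gene in SMFISH_TARGETS:
        expr = rng.random(n_cells) < expressor_fraction
        copies_true = np.where(
            expr, rng.normal(mu_on, 3.0, n_cells), rng.normal(mu_off, 0.5, n_cells)
        )
        df[f"{gene}_copies"], df[f"{gene}_intensity"] = _observe(copies_true)
        df[f"true_{gene}_expressor"] = expr
    return df


def simulate_low_rank(
    n_genes: int = 500,
    n_obs: int = 600,
    rank: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-negative block low-rank matrix plus noise, for rank selection.

    Genes and observations are partitioned into ``rank`` blocks; loadings
    are U(1, 2) within a block and U(0, 0.1) outside, giving a planted
    rank-``rank`` signal.  Gaussian noise (sd ``noise_sd``) is added and
    the matrix clipped at zero.  Returns (X, W_true, H_true).
    """
    rng = np.random.default_rng(seed)
    gb = rng.integers(0, rank, n_genes)
    ob = rng.integers(0, rank, n_obs)
    W = rng.uniform(0.0, 0.1, (n_genes, rank))
    W[np.arange(n_genes), gb] = rng.uniform(1.0, 2.0, n_genes)
    H = rng.uniform(0.0, 0.1, (rank, n_obs))
    H[ob, np.arange(n_obs)] = rng.uniform(1.0, 2.0, n_obs)
    X = np.clip(W @ H + rng.normal(0.0, noise_sd, (n_genes, n_obs)), 0.0, None)
    return X, W, H
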