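"""Seeded synthetic corpora with known ground truth.

The generator emulates the structure a curated single-cell corpus assumes:
several datasets over the same tissue(s), a Gamma-Poisson (negative
binomial) count model with per-cell library sizes, cell types labeled
against a small ontology at mixed granularity, planted marker genes with a
known fold-change, optional per-dataset sequencing-depth shifts (batch
effect), and planted QC failures — low-coverage cells, non-primary
duplicates and cells from a disallowed assay. Every quantity needed to
assert downstream behavior is returned alongside the data as ground truth.

Counts for cell i, gene g: Poisson(L_i * w_tg / sum_g w_tg) where w_tg is
the gene's Gamma-distributed relative expression, multiplied by the marker
fold-change in the marker's own type, and L_i ~ LogNormal is the library
size (times the dataset's depth factor when a batch effect is planted).
Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .ontology import OntologyGraph

#: Default cell-type ontology: a small immune subtree (child -> parent).
DEFAULT_TREE: tuple[tuple[str, str], ...] = (
    ("CL:0000542", "CL:0000000"),  # lymphocyte -> cell
    ("CL:0000236", "CL:0000542"),  # B cell -> lymphocyte
    ("CL:0000786", "CL:0000236"),  # plasma cell -> B cell
    ("CL:0000084", "CL:0000542"),  # T cell -> lymphocyte
    ("CL:0000576", "CL:0000000"),  # monocyte -> cell
    ("CL:0000775", "CL:0000000"),  # neutrophil -> cell
)

DEFAULT_LABELED_TYPES: tuple[str, ...] = (
    "CL:0000236",
    "CL:0000786",
    "CL:0000084",
    "CL:0000576",
    "CL:0000775",
)

#: An excluded full-length assay (requires gene-length normalization).
DISALLOWED_ASSAY = "EFO:0008931"  # Smart-seq2
#: Allow-listed assays assigned to datasets, cycling.
DATASET_ASSAYS = ("EFO:0009899", "EFO:0008722", "EFO:0009922", "EFO:0010550")


@dataclass
class SynthConfig:
    """Conditions of a synthetic corpus.

    Defaults give 3 datasets x 5 labeled types x 80 cells (240 cells per
    type corpus-wide) over 800 genes in one tissue, with 5 planted markers
    per type at 4-fold enrichment — enough cells and signal for marker
    recovery while keeping full runs fast.
    """

    n_datasets: int = 3
    tissues: tuple[str, ...] = ("UBERON:0002048",)
    cell_type_tree: tuple[tuple[str, str], ...] = DEFAULT_TREE
    labeled_types: tuple[str, ...] = DEFAULT_LABELED_TYPES
    cells_per_type: int | Mapping[str, int] = 80
    n_genes: int = 800
    gene_mean_shape: float = 2.0  # Gamma shape of relative expression
    gene_mean_scale: float = 1.0
    library_size: float = 5000.0  # median library size
    library_sigma: float = 0.35  # LogNormal sigma of library sizes
    markers_per_type: int = 5
    marker_fold: float = 4.0
    # Canonical markers are robustly detected genes; planted marker genes get
    # this baseline relative expression (vs a mean of shape*scale for the
    # rest) so they are quantifiable, not buried below the expression mask.
    marker_base_expr: float = 4.0
    batch_effect: float = 0.0  # sd of per-dataset log depth factors
    frac_low_coverage: float = 0.05
    frac_nonprimary: float = 0.05
    frac_bad_assay: float = 0.05
    frac_coarse_label: float = 0.1  # cells annotated at the parent term
    low_coverage_genes: int = 100  # expressed genes in a planted low-coverage cell
    min_normal_expressed: int = 520  # floor enforced for non-planted cells
    seed: int = 0

    def n_cells(self, cell_type: str) -> int:
        if isinstance(self.cells_per_type, Mapping):
            return int(self.cells_per_type[cell_type])
        return int(self.cells_per_type)

    def validate(self) -> OntologyGraph:
        if self.n_datasets < 1 or self.n_genes < 1 or self.markers_per_type < 0:
            raise ValueError("sizes must be positive")
        if not self.labeled_types:
            raise ValueError("no labeled cell types")
        if any(self.n_cells(ct) < 1 for ct in self.labeled_types):
            raise ValueError("cells_per_type must be >= 1")
        for frac in (
            self.frac_low_coverage,
            self.frac_nonprimary,
            self.frac_bad_assay,
            self.frac_coarse_label,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        graph = OntologyGraph.from_edges(self.cell_type_tree)  # raises on cycle
        missing = set(self.labeled_types) - graph.nodes
        if missing:
            raise ValueError(f"labeled types not in tree: {sorted(missing)}")
        if self.markers_per_type * len(self.labeled_types) > self.n_genes:
            raise ValueError("not enough genes to plant the requested markers")
        return graph


@dataclass
class SynthCorpus:
    """Generated datasets plus the ground truth that produced them."""

    datasets: list[AnnData]
    graph: OntologyGraph
    true_markers: pd.DataFrame  # tissue, cell_type, gene
    planted_removals: pd.DataFrame  # dataset_id, barcode, reason
    depth_factors: dict[str, float]
    config: SynthConfig = field(repr=False)


def generate_corpus(config: SynthConfig | None = None) -> SynthCorpus:
    """Generate a corpus; deterministic given ``config.seed``."""
    config = config or SynthConfig()
    graph = config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    genes = np.array([f"gene_{i:04d}" for i in range(config.n_genes)], dtype=object)
    rel_expr = rng.gamma(config.gene_mean_shape, config.gene_mean_scale, config.n_genes)
    rel_expr = np.maximum(rel_expr, 1e-6)

    marker_pool = rng.permutation(config.n_genes)
    marker_of: dict[str, np.ndarray] = {}
    pos = 0
    for ct in config.labeled_types:
        marker_of[ct] = marker_pool[pos : pos + config.markers_per_type]
        rel_expr[marker_of[ct]] = config.marker_base_expr
        pos += config.markers_per_type

    true_markers = pd.DataFrame(
        [
            (tissue, ct, genes[g])
            for tissue in config.tissues
            for ct in config.labeled_types
            for g in marker_of[ct]
        ],
        columns=["tissue", "cell_type", "gene"],
    )

    parent = {c: p for c, p in config.cell_type_tree}
    datasets: list[AnnData] = []
    removals: list[tuple[str, str, str]] = []
    depth_factors: dict[str, float] = {}

    for d in range(config.n_datasets):
        ds_id = f"dataset_{d}"
        depth = float(np.exp(config.batch_effect * rng.normal()))
        depth_factors[ds_id] = depth
        blocks, labels, tissues_col = [], [], []
        for tissue in config.tissues:
            for ct in config.labeled_types:
                n = config.n_cells(ct)
                w = rel_expr.copy()
                w[marker_of[ct]] *= config.marker_fold
                p = w / w.sum()
                lib = config.library_size * depth * np.exp(
                    rng.normal(0.0, config.library_sigma, n)
                )
                lam = lib[:, None] * p[None, :]
                blocks.append(rng.poisson(lam))
                labels += [ct] * n
                tissues_col += [tissue] * n
        counts = np.concatenate(blocks, axis=0)
        n_cells = counts.shape[0]
        labels = np.array(labels, dtype=object)
        tissues_col = np.array(tissues_col, dtype=object)
        barcodes = np.array([f"{ds_id}_cell{i:05d}" for i in range(n_cells)])

        # disjoint planted QC failures
        order = rng.permutation(n_cells)
        n_low = int(round(config.frac_low_coverage * n_cells))
        n_nonprim = int(round(config.frac_nonprimary * n_cells))
        n_bad = int(round(config.frac_bad_assay * n_cells))
        low_idx = order[:n_low]
        nonprim_idx = order[n_low : n_low + n_nonprim]
        bad_idx = order[n_low + n_nonprim : n_low + n_nonprim + n_bad]

        for i in low_idx:
            keep = rng.choice(config.n_genes, config.low_coverage_genes, replace=False)
            row = np.zeros(config.n_genes, dtype=counts.dtype)
            row[keep] = np.maximum(counts[i, keep], 1)
            counts[i] = row
        # keep unplanted cells comfortably above the coverage threshold
        normal = np.setdiff1d(np.arange(n_cells), low_idx)
        expressed = (counts[normal] > 0).sum(axis=1)
        for j in np.flatnonzero(expressed < config.min_normal_expressed):
            i = normal[j]
            zeros = np.flatnonzero(counts[i] == 0)
            need = config.min_normal_expressed - int((counts[i] > 0).sum())
            counts[i, rng.choice(zeros, need, replace=False)] = 1

        primary = np.ones(n_cells, dtype=bool)
        primary[nonprim_idx] = False
        assay = np.full(n_cells, DATASET_ASSAYS[d % len(DATASET_ASSAYS)], dtype=object)
        assay[bad_idx] = DISALLOWED_ASSAY

        n_coarse = int(round(config.frac_coarse_label * n_cells))
        coarse_idx = order[::-1][:n_coarse]  # disjoint ordering not required
        for i in coarse_idx:
            labels[i] = parent.get(labels[i], labels[i])

        removals += [(ds_id, barcodes[i], "low_coverage") for i in low_idx]
        removals += [(ds_id, barcodes[i], "nonprimary") for i in nonprim_idx]
        removals += [(ds_id, barcodes[i], "bad_assay") for i in bad_idx]

        obs = pd.DataFrame(
            {
                "organism": "NCBITaxon:9606",
                "tissue": tissues_col,
                "cell_type": labels,
                "assay": assay,
                "disease": "PATO:0000461",
                "sex": rng.choice(["PATO:0000383", "PATO:0000384"], n_cells),
                "self_reported_ethnicity": "HANCESTRO:0005",
                "development_stage": "HsapDv:0000087",
                "donor_id": f"donor_{d}",
                "suspension_type": "cell",
                "is_primary_data": primary,
            },
            index=barcodes,
        )
        adata = AnnData(
            X=sp.csr_matrix(counts.astype(np.int64)),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        adata.obsm["X_umap"] = rng.normal(size=(n_cells, 2))
        adata.uns["dataset_id"] = ds_id
        datasets.append(adata)

    return SynthCorpus(
        datasets=datasets,
        graph=graph,
        true_markers=true_markers,
        planted_removals=pd.DataFrame(
            removals, columns=["dataset_id", "barcode", "reason"]
        ),
        depth_factors=depth_factors,
        config=config,
    )


def generate_reference_markers(
    corpus: SynthCorpus, noise: float = 0.0, seed: int | None = None
) -> pd.DataFrame:
    """Reference marker table from the planted truth, optionally corrupted.

    A fraction ``noise`` of each type's reference genes is replaced with
    random non-marker genes, emulating the noisiness of externally curated
    marker tables. ``noise=0`` returns exactly the planted markers.
    """
    truth = corpus.true_markers
    if truth.empty:
        raise ValueError("corpus has no planted markers")
    if not 0 <= noise <= 1:
        raise ValueError("noise must lie in [0, 1]")
    if noise == 0:
        return truth.copy()
    rng = np.random.default_rng(
        corpus.config.seed + 1 if seed is None else seed
    )
    all_genes = np.array(
        [f"gene_{i:04d}" for i in range(corpus.config.n_genes)], dtype=object
    )
    non_markers = np.setdiff1d(all_genes, truth["gene"].unique())
    rows = []
    for (tissue, ct), grp in truth.groupby(["tissue", "cell_type"], sort=True):
        genes = grp["gene"].to_numpy().copy()
        n_swap = int(round(noise * len(genes)))
        if n_swap:
            swap_pos = rng.choice(len(genes), n_swap, replace=False)
            genes[swap_pos] = rng.choice(non_markers, n_swap, replace=False)
        rows += [(tissue, ct, g) for g in genes]
    return pd.DataFrame(rows, columns=["tissue", "cell_type", "gene"])
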