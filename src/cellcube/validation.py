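"""Validation statistics: marker recall and batch-effect ANOVA.

Two study designs are implemented:

* **Marker recall** — computationally derived markers for a cell type are
  compared with a reference marker table. Recall is the fraction of
  reference genes recovered among the predicted top-k; the probability of
  reaching the observed overlap by chance is the upper tail of a
  hypergeometric distribution over the tissue's gene universe. Cell types
  colinear in the ontology (one an ancestor of another) are pruned to the
  more specific term before evaluation.

* **Batch effects** — a one-way repeated-measures ANOVA treats the per-gene
  average expression (zeros excluded) as the dependent variable, the genes
  of a set (markers or housekeeping) as the repeated subjects, and a batch
  covariate (dataset id or sequencing assay) as the within-subject factor.
  Because not every gene appears at every covariate level, the design may be
  unbalanced; genes missing a level are dropped (complete case). The study
  can run on raw counts, ln(counts-per-million + 1), or per-cell quantile
  normalization to compare how normalization mitigates batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import hypergeom

from .aggregate import CubePart
from .markers import TOP_K, compute_markers, tissue_group_stats
from .ontology import OntologyGraph, prune_colinear
from .preprocess import CPM_SCALE_FACTOR, PreprocessConfig, preprocess_dataset


@dataclass
class RecallResult:
    tissue: str
    cell_type: str
    n_reference: int
    n_predicted: int
    n_overlap: int
    recall: float
    p_chance: float


@dataclass
class AnovaResult:
    gene_set: str
    cell_type: str
    covariate: str
    F: float
    p: float
    n_levels: int


# ----------------------------------------------------------- marker recall


def marker_recall(
    predicted: Iterable[str],
    reference: Iterable[str],
    universe_size: int,
    tissue: str = "",
    cell_type: str = "",
) -> RecallResult:
    """Recall of a reference marker set by a predicted set, with chance level.

    ``p_chance`` is P[X >= overlap] for X ~ Hypergeometric(universe_size,
    n_reference, n_predicted): the chance of drawing at least the observed
    number of reference genes when picking ``n_predicted`` genes uniformly
    from the universe.
    """
    predicted = set(predicted)
    reference = set(reference)
    if not reference:
        raise ValueError("reference marker set is empty")
    if len(predicted) > universe_size or len(reference) > universe_size:
        raise ValueError("universe smaller than a gene set")
    overlap = len(predicted & reference)
    p = float(hypergeom.sf(overlap - 1, universe_size, len(reference), len(predicted)))
    return RecallResult(
        tissue=tissue,
        cell_type=cell_type,
        n_reference=len(reference),
        n_predicted=len(predicted),
        n_overlap=overlap,
        recall=overlap / len(reference),
        p_chance=min(1.0, p),
    )


def recall_study(
    parts: Sequence[CubePart],
    reference_table: pd.DataFrame,
    graph: OntologyGraph,
    k: int = TOP_K,
    seed: int = 0,
    reps: int = 100,
    variant: str = "student",
    min_cells: int = 5,
) -> pd.DataFrame:
    """Marker-recall study over a corpus against a reference marker table.

    ``reference_table`` has columns ``tissue``, ``cell_type``, ``gene``.
    Within each tissue, colinear reference cell types are pruned to the more
    specific term; markers are then derived per remaining type (Student's t
    by default, matching how such evaluations are typically run with
    off-the-shelf differential-expression routines) and recall computed over
    the tissue's gene universe. Tissues or types absent from the corpus are
    skipped. Returns one row per evaluated type; ``mean recall`` is the
    column mean of ``recall``.
    """
    parts = list(parts)
    rows = []
    for tissue, ref_tissue in reference_table.groupby("tissue"):
        stats = tissue_group_stats(parts, str(tissue))
        if not stats.cell_types:
            continue
        universe = len(stats.genes)
        ref_types = set(ref_tissue["cell_type"]) & set(stats.cell_types)
        known = ref_types & graph.nodes
        evaluated = prune_colinear(known, graph) | (ref_types - known)
        for ct in sorted(evaluated):
            reference = set(ref_tissue.loc[ref_tissue["cell_type"] == ct, "gene"])
            predicted = compute_markers(
                stats,
                str(tissue),
                ct,
                k=k,
                seed=seed,
                reps=reps,
                variant=variant,
                min_cells=min_cells,
            )["gene"]
            if predicted.empty:
                continue
            rows.append(
                vars(
                    marker_recall(
                        predicted, reference, universe, str(tissue), ct
                    )
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "cell_type",
            "n_reference",
            "n_predicted",
            "n_overlap",
            "recall",
            "p_chance",
        ],
    )


# ------------------------------------------------------- repeated-measures


def rm_anova(long_table: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on per-gene average expression.

    ``long_table`` columns: ``gene`` (the repeated subject),
    ``covariate_level`` and ``avg_expression``. Genes missing any covariate
    level are dropped (complete case); at least 2 levels and 2 complete
    genes are required. When every gene is constant across levels there is
    no covariate effect at all and (F, p) = (0, 1) by convention.
    """
    df = long_table.rename(columns=str).copy()
    levels = df["covariate_level"].unique()
    if len(levels) < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 covariate levels")
    wide = df.pivot_table(
        index="gene", columns="covariate_level", values="avg_expression"
    )
    wide = wide.dropna(axis=0, how="any")
    if wide.shape[0] < 2:
        raise ValueError("fewer than 2 genes observed at every covariate level")
    complete = wide.reset_index().melt(
        id_vars="gene", var_name="covariate_level", value_name="avg_expression"
    )
    ss_effect = (
        (wide.mean(axis=0) - wide.to_numpy().mean()) ** 2
    ).sum() * wide.shape[0]
    if np.isclose(ss_effect, 0.0):
        return AnovaResult("", "", "", F=0.0, p=1.0, n_levels=len(wide.columns))
    aov = pg.rm_anova(
        data=complete,
        dv="avg_expression",
        within="covariate_level",
        subject="gene",
        detailed=False,
    )
    F = float(aov.loc[0, "F"])
    p = float(aov.loc[0, "p_unc"])
    return AnovaResult("", "", "", F=F, p=p, n_levels=int(wide.shape[1]))


def average_expression_by_level(
    datasets: Sequence[AnnData],
    cell_type: str,
    genes: Sequence[str],
    covariate: str,
    normalization: str = "cptt_log",
    scale_factor: float = CPM_SCALE_FACTOR,
) -> pd.DataFrame:
    """Per-gene average expression at each covariate level, excluding zeros.

    ``covariate`` is ``dataset_id`` (one level per dataset) or an ``obs``
    column such as ``assay``. Cells of other types are ignored; QC masking is
    not applied — only zero values are excluded from the averages, matching
    the batch-study convention. Returns a long table (gene,
    covariate_level, avg_expression) with missing gene/level pairs absent.
    """
    cfg = PreprocessConfig(
        method={"raw": "raw", "cptt_log": "cptt_log", "quantile": "quantile"}[
            normalization
        ],
        scale_factor=scale_factor,
        do_mask=False,
        do_assay=False,
        do_low_coverage=True,
        do_dedup=True,
    )
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for i, adata in enumerate(datasets):
        res = preprocess_dataset(adata, cfg)
        obs = adata.obs.iloc[res.retained]
        if covariate == "dataset_id":
            level_values = pd.Series(
                str(adata.uns.get("dataset_id", f"dataset_{i}")), index=obs.index
            )
        else:
            level_values = obs[covariate].astype(str)
        in_type = (obs["cell_type"].astype(str) == cell_type).to_numpy()
        if not in_type.any():
            continue
        gene_idx = {g: j for j, g in enumerate(adata.var_names)}
        cols = [gene_idx[g] for g in genes if g in gene_idx]
        present_genes = [g for g in genes if g in gene_idx]
        values = res.normalized.values[in_type][:, cols]
        for level in level_values[in_type].unique():
            rows = (level_values[in_type] == level).to_numpy()
            block = sp.csr_matrix(values[rows])
            nz = block.copy()
            nz.data = np.ones_like(nz.data)
            s = np.asarray(block.sum(axis=0)).ravel()
            n = np.asarray(nz.sum(axis=0)).ravel()
            for g, sg, ng in zip(present_genes, s, n):
                key = (g, str(level))
                sums[key] = sums.get(key, 0.0) + float(sg)
                counts[key] = counts.get(key, 0) + int(ng)
    rows = [
        {
            "gene": g,
            "covariate_level": lvl,
            "avg_expression": sums[(g, lvl)] / counts[(g, lvl)],
        }
        for (g, lvl) in sums
        if counts[(g, lvl)] > 0
    ]
    return pd.DataFrame(rows, columns=["gene", "covariate_level", "avg_expression"])


def batch_effect_study(
    datasets: Sequence[AnnData],
    covariate: str = "dataset_id",
    normalization: str = "cptt_log",
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    cell_types: Sequence[str] | None = None,
    scale_factor: float = CPM_SCALE_FACTOR,
) -> pd.DataFrame:
    """Repeated-measures ANOVA per (cell type, gene set) across a covariate.

    For each cell type and each named gene set, the per-gene non-zero
    average expression at every covariate level feeds :func:`rm_anova`.
    Raises when the covariate takes a single level in the corpus.
    """
    if gene_sets is None:
        raise ValueError("supply gene_sets as {label: [genes]}")
    if covariate == "dataset_id":
        levels = {
            str(d.uns.get("dataset_id", i)) for i, d in enumerate(datasets)
        }
    else:
        levels = {
            str(v) for d in datasets for v in d.obs[covariate].astype(str).unique()
        }
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} is constant across the corpus")
    if cell_types is None:
        cell_types = sorted(
            {
                str(v)
                for d in datasets
                for v in d.obs["cell_type"].astype(str).unique()
            }
        )
    rows = []
    for ct in cell_types:
        for label, genes in gene_sets.items():
            table = average_expression_by_level(
                datasets, ct, list(genes), covariate, normalization, scale_factor
            )
            if table.empty:
                continue
            try:
                res = rm_anova(table)
            except ValueError:
                continue
            rows.append(
                AnovaResult(
                    gene_set=label,
                    cell_type=ct,
                    covariate=covariate,
                    F=res.F,
                    p=res.p,
                    n_levels=res.n_levels,
                )
            )
    return pd.DataFrame([vars(r) for r in rows])
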