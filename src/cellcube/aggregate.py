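"""Corpus-level expression cubes.

The cube is the data behind the cross-corpus heatmap: for every
(tissue, cell type, gene) — optionally stratified by extra metadata facets
such as sex or disease — it stores the mean of the present (unmasked,
non-zero) normalized values, the number of cells expressing the gene, and
the number of QC-passing cells in the stratum. Dot color in the heatmap is
``mean_nonzero``; dot size is ``n_expressing / n_cells``.

``n_cells`` is a property of the stratum (all QC-passing cells of the
tissue/cell-type/facet combination), identical across the stratum's genes.
Datasets are concatenated along the gene axis by id union: a gene not
measured by a dataset is *missing* (not zero) for its cells and never
contributes to non-zero means or expressing counts.

Cubes are mergeable: building per dataset and merging by sums and counts is
exactly equivalent to building on the concatenated corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ontology import OntologyGraph
from .preprocess import NormalizedMatrix

KEY_COLUMNS = ["tissue", "cell_type", "gene"]
VALUE_COLUMNS = ["mean_nonzero", "n_expressing", "n_cells"]


@dataclass
class CubePart:
    """One dataset's contribution to a cube."""

    normalized: NormalizedMatrix
    metadata: pd.DataFrame  # aligned to the normalized rows
    genes: Sequence[str]


def build_cube(
    parts: Iterable[CubePart] | CubePart,
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Build the expression cube from one or more preprocessed datasets.

    ``group_by`` names extra metadata fields; strata are the exact cross
    product of the values present in the data. Keys with no expressing cell
    are absent from the result.
    """
    if isinstance(parts, CubePart):
        parts = [parts]
    longs, strata = [], []
    for i, part in enumerate(parts):
        lg, st = _cube_one(part, group_by, part_id=i)
        longs.append(lg)
        strata.append(st)
    if not longs:
        return _empty_cube(group_by)
    return _finalize(
        pd.concat(longs, ignore_index=True),
        pd.concat(strata, ignore_index=True),
        group_by,
    )


def _empty_cube(group_by: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=KEY_COLUMNS + list(group_by) + VALUE_COLUMNS)


def _cube_one(
    part: CubePart, group_by: Sequence[str], part_id: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long per-(stratum, gene) sums/counts plus a per-stratum cell table."""
    obs = part.metadata
    for f in ("tissue", "cell_type", *group_by):
        if f not in obs.columns:
            raise KeyError(f"unknown facet/metadata field: {f!r}")
    values = (
        part.normalized.values
        if isinstance(part.normalized, NormalizedMatrix)
        else sp.csr_matrix(part.normalized)
    )
    if values.shape[0] != len(obs):
        raise ValueError("metadata not aligned to normalized matrix")

    key_cols = ["tissue", "cell_type", *group_by]
    keys = obs[key_cols].astype(str)
    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(keys), sort=True)
    n_strata = len(uniques)
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_strata, len(codes)),
    )
    sums = np.asarray((indicator @ values).todense())
    ones = values.copy()
    ones.data = np.ones_like(ones.data)
    n_expr = np.asarray((indicator @ ones).todense())
    n_cells = np.bincount(codes, minlength=n_strata)

    strata = pd.DataFrame(list(uniques), columns=key_cols)
    strata["n_cells"] = n_cells.astype(int)
    strata["part"] = part_id

    genes = np.asarray(part.genes, dtype=object)
    rows = []
    for s in range(n_strata):
        df = pd.DataFrame(
            {
                "gene": genes,
                "sum_nonzero": sums[s],
                "n_expressing": n_expr[s].astype(int),
            }
        )
        for col in key_cols:
            df[col] = strata.at[s, col]
        rows.append(df)
    long = pd.concat(rows, ignore_index=True)
    return long[key_cols + ["gene", "sum_nonzero", "n_expressing"]], strata


def _finalize(
    long: pd.DataFrame, strata: pd.DataFrame, group_by: Sequence[str]
) -> pd.DataFrame:
    stratum_key = ["tissue", "cell_type", *group_by]
    key = [*stratum_key, "gene"]
    agg = long.groupby(key, sort=True, as_index=False)[
        ["sum_nonzero", "n_expressing"]
    ].sum()
    agg = agg[agg["n_expressing"] > 0].copy()
    agg["mean_nonzero"] = agg["sum_nonzero"] / agg["n_expressing"]
    sizes = strata.groupby(stratum_key, sort=True, as_index=False)["n_cells"].sum()
    agg = agg.merge(sizes, on=stratum_key, how="left")
    agg["n_cells"] = agg["n_cells"].astype(int)
    return agg[KEY_COLUMNS + list(group_by) + VALUE_COLUMNS].reset_index(drop=True)


def _split_cube(cube: pd.DataFrame, part_id: int):
    """Recover (long sums, stratum sizes) from a finalized cube."""
    group_by = [c for c in cube.columns if c not in KEY_COLUMNS + VALUE_COLUMNS]
    stratum_key = ["tissue", "cell_type", *group_by]
    long = cube.copy()
    long["sum_nonzero"] = long["mean_nonzero"] * long["n_expressing"]
    long = long[[*stratum_key, "gene", "sum_nonzero", "n_expressing"]]
    strata = cube[stratum_key + ["n_cells"]].drop_duplicates(stratum_key).copy()
    strata["part"] = part_id
    return long, strata, group_by


def merge_cubes(cubes: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge cubes built from disjoint sets of datasets.

    Exact: per-key sums are reconstructed from means and counts and added,
    stratum cell counts are added per stratum, and means recomputed — the
    result equals a cube built on the union of the underlying datasets
    (provided every stratum had at least one expressed gene per cube, so
    its size is recoverable).
    """
    longs, stratas = [], []
    group_by: list[str] = []
    for i, cube in enumerate(cubes):
        long, strata, group_by = _split_cube(cube, i)
        longs.append(long)
        stratas.append(strata)
    if not longs:
        return _empty_cube([])
    return _finalize(
        pd.concat(longs, ignore_index=True),
        pd.concat(stratas, ignore_index=True),
        group_by,
    )


def cube_rollup(cube: pd.DataFrame, graph: OntologyGraph) -> pd.DataFrame:
    """Roll the cube up the cell-type ontology.

    Each annotated term's sums of non-zero expression, expressing-cell
    counts and stratum cell counts are attributed to every ancestor term
    (set semantics via single-label attribution), and ancestor means are
    recomputed from the rolled sums — not by averaging per-term means.
    """
    if cube.empty:
        return cube.copy()
    long, strata, group_by = _split_cube(cube, 0)
    terms = cube["cell_type"].unique()
    mapping = pd.DataFrame(
        [(t, a) for t in terms for a in graph.ancestors(t)],
        columns=["cell_type", "rolled_type"],
    )

    def lift(df):
        out = df.merge(mapping, on="cell_type").drop(columns=["cell_type"])
        return out.rename(columns={"rolled_type": "cell_type"})

    strata = lift(strata)
    strata["part"] = np.arange(len(strata))  # each annotated stratum counted once
    return _finalize(lift(long), strata, group_by)
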