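"""Corpus I/O: datasets, ontologies, cubes and marker tables; chunked reads.

Datasets are exchanged either as H5AD containers (raw counts in a designated
layer, default ``"raw"``) or as MatrixMarket triplets
(``matrix.mtx`` + ``cells.tsv`` + ``genes.tsv``). MatrixMarket coordinates are
1-based on disk and converted to the package's 0-based internal indexing.

:func:`iter_chunks` provides the streaming contract used by
:mod:`cellcube.streaming`: fixed-size blocks of cells, in order, whose
concatenation reproduces the dataset exactly, so that out-of-core statistics
can be computed with memory bounded by one chunk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData
import anndata

from .ontology import OntologyGraph
from .schema import get_counts

EMBEDDING_PREFIX = "X_"


class ParseError(ValueError):
    """Malformed input file (distinct from schema validation failure)."""


# ---------------------------------------------------------------- datasets


def read_dataset(path: str | Path, format: str | None = None) -> AnnData:
    """Read one dataset from ``path``.

    ``format`` is ``"h5ad"`` or ``"mtx_triplet"``; when omitted it is
    inferred (a directory or a ``.mtx`` file means the triplet layout).
    Sparse representation is preserved.
    """
    path = Path(path)
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "mtx_triplet"
    if format == "h5ad":
        if not path.exists():
            raise FileNotFoundError(path)
        return anndata.read_h5ad(path)
    if format == "mtx_triplet":
        return _read_mtx_triplet(path)
    raise ValueError(f"unknown format: {format!r}")


def write_dataset(adata: AnnData, path: str | Path, format: str = "h5ad") -> Path:
    """Write one dataset; columns and gene order are emitted deterministically."""
    path = Path(path)
    if format == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
        return path
    if format == "mtx_triplet":
        return _write_mtx_triplet(adata, path)
    raise ValueError(f"unknown format: {format!r}")


def _read_mtx_triplet(folder: Path) -> AnnData:
    folder = Path(folder)
    mtx = folder / "matrix.mtx"
    cells = folder / "cells.tsv"
    genes = folder / "genes.tsv"
    for f in (mtx, cells, genes):
        if not f.exists():
            raise FileNotFoundError(f)
    try:
        # scipy reads MatrixMarket 1-based coordinates into 0-based arrays
        mat = sp.csr_matrix(scipy.io.mmread(mtx)).T  # file is genes x cells
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{mtx}: {exc}") from exc
    obs = pd.read_csv(cells, sep="\t", index_col=0, dtype={0: str})
    obs.index = obs.index.astype(str)
    if "is_primary_data" in obs.columns:
        obs["is_primary_data"] = obs["is_primary_data"].astype(bool)
    var = pd.read_csv(genes, sep="\t", index_col=0, dtype={0: str})
    var.index = var.index.astype(str)
    if mat.shape[0] == 0:
        mat = sp.csr_matrix((len(obs), len(var)), dtype=np.int64)
    if mat.shape != (len(obs), len(var)):
        raise ParseError(
            f"{mtx}: matrix shape {mat.shape} does not match "
            f"{len(obs)} cells x {len(var)} genes"
        )
    adata = AnnData(X=mat, obs=obs, var=var)
    for emb_file in sorted(folder.glob("embedding_*.tsv")):
        name = emb_file.stem.removeprefix("embedding_")
        adata.obsm[EMBEDDING_PREFIX + name] = (
            pd.read_csv(emb_file, sep="\t", index_col=0).to_numpy(dtype=float)
        )
    uns_file = folder / "uns.json"
    if uns_file.exists():
        adata.uns.update(json.loads(uns_file.read_text()))
    return adata


def _write_mtx_triplet(adata: AnnData, folder: Path) -> Path:
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    counts = get_counts(adata)
    mat = sp.coo_matrix(counts).T  # genes x cells on disk
    scipy.io.mmwrite(folder / "matrix.mtx", mat)
    adata.obs.to_csv(folder / "cells.tsv", sep="\t", index_label="barcode")
    adata.var.to_csv(folder / "genes.tsv", sep="\t", index_label="gene")
    for name, emb in adata.obsm.items():
        short = str(name).removeprefix(EMBEDDING_PREFIX)
        pd.DataFrame(np.asarray(emb), index=adata.obs_names).to_csv(
            folder / f"embedding_{short}.tsv", sep="\t", index_label="barcode"
        )
    if adata.uns:
        serializable = {
            k: v for k, v in adata.uns.items() if isinstance(v, (str, int, float, bool, list))
        }
        (folder / "uns.json").write_text(json.dumps(serializable, indent=1))
    return folder


# ----------------------------------------------------------------- chunks


@dataclass
class Chunk:
    """A contiguous block of cells from one dataset."""

    row_offset: int
    cell_ids: list[str]
    submatrix: sp.csr_matrix
    metadata_rows: pd.DataFrame


def iter_chunks(
    adata: AnnData, chunk_size: int, layer: str | None = None
) -> Iterator[Chunk]:
    """Yield the dataset as ordered blocks of at most ``chunk_size`` cells.

    Chunks partition the cell axis in order; concatenating their submatrices
    and metadata reproduces the dataset exactly.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    matrix = adata.layers[layer] if layer else get_counts(adata)
    matrix = sp.csr_matrix(matrix)
    n = adata.n_obs
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        yield Chunk(
            row_offset=start,
            cell_ids=list(adata.obs_names[start:stop]),
            submatrix=matrix[start:stop],
            metadata_rows=adata.obs.iloc[start:stop],
        )


# --------------------------------------------------------------- ontology


def read_ontology(path: str | Path) -> OntologyGraph:
    """Read a cell-type ontology from a two-column child→parent edge list.

    Lines are ``child_id<TAB>parent_id``; a header line is tolerated when its
    first field is ``child``. Cycles are an error; a parent that never appears
    as a child elsewhere is fine (it is simply a root), but edges referencing
    an empty id raise.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected 2 tab-separated fields")
        child, parent = (p.strip() for p in parts)
        if ln == 1 and child.lower() in {"child", "child_id"}:
            continue
        if not child or not parent:
            raise ParseError(f"{path}:{ln}: empty term id")
        edges.append((child, parent))
    return OntologyGraph.from_edges(edges)


def write_ontology(graph: OntologyGraph, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["child\tparent"]
    lines += [f"{c}\t{p}" for c, p in sorted(graph.graph.edges())]
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------- cubes & marker tables

CUBE_KEY_COLUMNS = ["tissue", "cell_type", "gene"]
CUBE_VALUE_COLUMNS = ["mean_nonzero", "n_expressing", "n_cells"]


def write_cube(cube: pd.DataFrame, path: str | Path) -> Path:
    """Write an expression cube as long-format TSV with deterministic order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    facets = [
        c for c in cube.columns if c not in CUBE_KEY_COLUMNS + CUBE_VALUE_COLUMNS
    ]
    cols = CUBE_KEY_COLUMNS + facets + CUBE_VALUE_COLUMNS
    out = cube[cols].sort_values(CUBE_KEY_COLUMNS + facets, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_cube(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_markers(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a marker table (tissue, cell_type, rank, gene, effect) as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["tissue", "cell_type", "rank", "gene", "effect"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_markers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
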