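"""Quality-control filters and normalization for corpus aggregation.

The pipeline, applied per dataset and in this order:

1. keep only cells demarcated as primary data (duplicate removal),
2. drop low-coverage cells expressing fewer than 500 genes,
3. keep only cells from UMI-based assays that need no gene-length
   normalization (a fixed EFO allow-list),
4. normalize each cell to ln(CPTT + 1), where CPTT is counts per ten
   thousand: value = ln(count / cell_total * 10000 + 1),
5. set ultra-low expression values (<= 3 after normalization) to *missing* —
   absent from the sparse structure, never coerced to zero — so downstream
   non-zero means are not dragged down by noise.

A rank-based alternative (:func:`normalize_quantile`, per-cell rankit
transform) is provided for normalization-comparison studies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.special import ndtri

from .schema import get_counts


def _load_allowlist() -> frozenset[str]:
    with resources.files("cellcube.data").joinpath("assay_allowlist.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return frozenset(table["efo_id"])


#: EFO ids of sequencing assays whose counts are comparable without
#: gene-length normalization (UMI-based and droplet protocols).
ASSAY_ALLOWLIST: frozenset[str] = _load_allowlist()

DEFAULT_SCALE_FACTOR = 10_000.0
#: Scale factor used by the batch-effect analyses (counts per million).
CPM_SCALE_FACTOR = 1_000_000.0


@dataclass
class NormalizedMatrix:
    """Cells x genes matrix of present (non-missing) normalized values.

    Stored sparse entries are the *present* values; structural zeros mean
    "missing or not expressed" and never enter non-zero means. After masking,
    every present value exceeds ``mask_threshold``.
    """

    values: sp.csr_matrix
    scale_factor: float = DEFAULT_SCALE_FACTOR
    provenance: list[str] = field(default_factory=list)
    mask_threshold: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PreprocessConfig:
    min_genes: int = 500
    assay_allowlist: frozenset[str] = ASSAY_ALLOWLIST
    scale_factor: float = DEFAULT_SCALE_FACTOR
    mask_threshold: float = 3.0
    mask_scale: str = "normalized"  # or "raw"
    method: str = "cptt_log"  # "cptt_log" | "quantile" | "raw"
    do_dedup: bool = True
    do_low_coverage: bool = True
    do_assay: bool = True
    do_mask: bool = True


@dataclass
class PreprocessResult:
    retained: np.ndarray  # indices into the original cell axis
    normalized: NormalizedMatrix
    removed: dict[str, int]  # cells removed per step


# ----------------------------------------------------------------- filters


def dedup_primary(cells: pd.DataFrame) -> np.ndarray:
    """Indices of cells demarcated as primary data."""
    flags = cells["is_primary_data"].astype(bool).to_numpy()
    return np.flatnonzero(flags)


def filter_low_coverage(counts, min_genes: int = 500) -> np.ndarray:
    """Indices of cells expressing (raw count > 0) at least ``min_genes`` genes.

    A cell with exactly ``min_genes`` expressed genes is retained; the filter
    excludes strictly fewer.
    """
    counts = sp.csr_matrix(counts)
    n_expressed = counts.getnnz(axis=1)
    return np.flatnonzero(n_expressed >= min_genes)


def filter_assay(
    cells: pd.DataFrame, allow_list: frozenset[str] | set[str] = ASSAY_ALLOWLIST
) -> np.ndarray:
    """Indices of cells whose assay CURIE is on the allow-list."""
    if not allow_list:
        raise ValueError("empty assay allow-list (override explicitly to disable)")
    keep = cells["assay"].astype(str).isin(allow_list).to_numpy()
    return np.flatnonzero(keep)


# ----------------------------------------------------------- normalization


def normalize_cptt(counts, scale_factor: float = DEFAULT_SCALE_FACTOR) -> sp.csr_matrix:
    """ln(CPTT + 1) transform of raw counts, row-wise.

    value[c, g] = ln(count[c, g] / total[c] * scale_factor + 1). Monotone in
    the count at fixed total; zero counts map to ln(1) = 0 and stay
    structural zeros. Rows with zero total are rejected (they cannot occur
    after the low-coverage filter).
    """
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals == 0) and counts.shape[0] > 0:
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"cell {bad} has zero total count; cannot normalize")
    out = counts.copy()
    row_of = np.repeat(np.arange(counts.shape[0]), np.diff(counts.indptr))
    out.data = np.log1p(counts.data / totals[row_of] * scale_factor)
    return out


def normalize_quantile(counts) -> sp.csr_matrix:
    """Per-cell rankit transform of the non-zero counts.

    The m non-zero entries of a cell are mapped by rank r (average ranks for
    ties) to standard-normal quantiles ndtri((r - 0.5) / m); zeros stay zero.
    Rank order is preserved. Used only for normalization comparisons.
    """
    from scipy.stats import rankdata

    counts = sp.csr_matrix(counts, dtype=float)
    out = counts.copy()
    for i in range(counts.shape[0]):
        lo, hi = counts.indptr[i], counts.indptr[i + 1]
        m = hi - lo
        if m == 0:
            continue
        ranks = rankdata(counts.data[lo:hi], method="average")
        out.data[lo:hi] = ndtri((ranks - 0.5) / m)
    return out


def mask_low_expression(
    normalized: NormalizedMatrix,
    threshold: float = 3.0,
    raw_counts=None,
    scale: str = "normalized",
) -> NormalizedMatrix:
    """Set ultra-low expression values to missing.

    With ``scale="normalized"`` (default) a present value v becomes missing
    iff v <= threshold, on the ln(CPTT+1) scale. With ``scale="raw"`` the
    decision is made on the aligned raw count instead. Masked entries leave
    the sparse structure entirely; the operation is idempotent.
    """
    values = normalized.values.copy()
    if scale == "normalized":
        values.data[values.data <= threshold] = 0.0
    elif scale == "raw":
        if raw_counts is None:
            raise ValueError("scale='raw' requires the aligned raw count matrix")
        raw = sp.csr_matrix(raw_counts)
        if raw.shape != values.shape:
            raise ValueError("raw counts not aligned to normalized matrix")
        values.data[_aligned_low(values, raw, threshold)] = 0.0
    else:
        raise ValueError(f"unknown mask scale: {scale!r}")
    values.eliminate_zeros()
    step = f"mask_low_expression(threshold={threshold}, scale={scale})"
    prov = list(normalized.provenance)
    if not prov or prov[-1] != step:
        prov.append(step)
    return replace(
        normalized, values=values, provenance=prov, mask_threshold=threshold
    )


def _aligned_low(values: sp.csr_matrix, raw: sp.csr_matrix, threshold: float):
    """Boolean over ``values.data`` marking entries whose raw count <= threshold."""
    mask = np.zeros(values.data.shape, dtype=bool)
    for i in range(values.shape[0]):
        vlo, vhi = values.indptr[i], values.indptr[i + 1]
        rlo, rhi = raw.indptr[i], raw.indptr[i + 1]
        raw_row = dict(zip(raw.indices[rlo:rhi], raw.data[rlo:rhi]))
        for k in range(vlo, vhi):
            if raw_row.get(values.indices[k], 0) <= threshold:
                mask[k] = True
    return mask


# ----------------------------------------------------------------- driver


def preprocess_dataset(
    adata: AnnData, config: PreprocessConfig | None = None
) -> PreprocessResult:
    """Run the full pipeline on one dataset.

    Filters compose in the stated order on the original cell axis; the
    returned normalized matrix covers only retained cells, with provenance
    recording each applied step.
    """
    config = config or PreprocessConfig()
    counts = sp.csr_matrix(get_counts(adata))
    obs = adata.obs
    retained = np.arange(adata.n_obs)
    removed: dict[str, int] = {}
    provenance: list[str] = []

    if config.do_dedup:
        keep = dedup_primary(obs.iloc[retained])
        removed["dedup_primary"] = len(retained) - len(keep)
        retained = retained[keep]
        provenance.append("dedup_primary")
    if config.do_low_coverage:
        keep = filter_low_coverage(counts[retained], config.min_genes)
        removed["filter_low_coverage"] = len(retained) - len(keep)
        retained = retained[keep]
        provenance.append(f"filter_low_coverage(min_genes={config.min_genes})")
    if config.do_assay:
        keep = filter_assay(obs.iloc[retained], config.assay_allowlist)
        removed["filter_assay"] = len(retained) - len(keep)
        retained = retained[keep]
        provenance.append("filter_assay")

    sub = counts[retained]
    if config.method == "cptt_log":
        values = normalize_cptt(sub, config.scale_factor)
        provenance.append(f"normalize_cptt(scale_factor={config.scale_factor:g})")
    elif config.method == "quantile":
        values = normalize_quantile(sub)
        provenance.append("normalize_quantile")
    elif config.method == "raw":
        values = sp.csr_matrix(sub, dtype=float)
        provenance.append("raw")
    else:
        raise ValueError(f"unknown normalization method: {config.method!r}")

    norm = NormalizedMatrix(
        values=values, scale_factor=config.scale_factor, provenance=provenance
    )
    if config.do_mask:
        norm = mask_low_expression(
            norm,
            threshold=config.mask_threshold,
            raw_counts=sub if config.mask_scale == "raw" else None,
            scale=config.mask_scale,
        )
    return PreprocessResult(retained=retained, normalized=norm, removed=removed)


def run_preprocess(
    datasets: Mapping[str, AnnData] | Sequence[AnnData],
    config: PreprocessConfig | None = None,
) -> dict[str, PreprocessResult]:
    """Preprocess every dataset independently; order of datasets is immaterial."""
    if not isinstance(datasets, Mapping):
        datasets = {
            str(d.uns.get("dataset_id", i)): d for i, d in enumerate(datasets)
        }
    return {name: preprocess_dataset(d, config) for name, d in datasets.items()}
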