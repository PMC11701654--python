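"""Minimal cell-level metadata schema and dataset validation.

A contributed dataset is an :class:`anndata.AnnData` whose raw count matrix
lives in a designated layer (default ``"raw"``, falling back to ``X``), whose
``obs`` table carries eleven required per-cell fields, and which provides at
least one two-dimensional embedding in ``obsm``.

Eight of the required fields are ontology CURIEs (``PREFIX:identifier``);
``donor_id`` is free text, ``suspension_type`` is a closed vocabulary and
``is_primary_data`` is a per-cell boolean that must mark each observation as
primary exactly once across an entire corpus, so that corpus-wide
aggregations never count the same cell twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*:\S+$")

#: Default allowed CURIE prefixes per ontology-typed field.
DEFAULT_PREFIXES: dict[str, tuple[str, ...]] = {
    "organism": ("NCBITaxon",),
    "tissue": ("UBERON",),
    "cell_type": ("CL",),
    "assay": ("EFO",),
    "disease": ("MONDO", "PATO"),
    "sex": ("PATO",),
    "self_reported_ethnicity": ("HANCESTRO",),
    "development_stage": ("HsapDv", "MmusDv", "UBERON"),
}

SUSPENSION_TYPES = ("cell", "nucleus", "na")

#: The 11 required per-cell fields.
REQUIRED_FIELDS: tuple[str, ...] = tuple(DEFAULT_PREFIXES) + (
    "donor_id",
    "suspension_type",
    "is_primary_data",
)


@dataclass
class SchemaConfig:
    """Configuration of the cell-level schema.

    Parameters
    ----------
    prefixes
        Allowed CURIE prefix(es) for each ontology-typed field. Fields may be
        added or re-prefixed; the schema is extensible by design.
    counts_layer
        Name of the raw-counts layer; ``X`` is used when absent.
    ontology_terms
        Optional set of known cell-type terms. When supplied, ``cell_type``
        values must be members (term-existence checking); otherwise only the
        CURIE syntax is enforced.
    """

    prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREFIXES)
    )
    counts_layer: str = "raw"
    ontology_terms: frozenset[str] | None = None

    @property
    def required_fields(self) -> tuple[str, ...]:
        return tuple(self.prefixes) + (
            "donor_id",
            "suspension_type",
            "is_primary_data",
        )


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning" | "info"
    location: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def add(self, severity: str, location: str, message: str) -> None:
        self.issues.append(Issue(severity, location, message))

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "issues": [vars(i) for i in self.issues],
        }


def get_counts(adata: AnnData, layer: str = "raw"):
    """Return the raw count matrix (the named layer, else ``X``)."""
    if layer in adata.layers:
        return adata.layers[layer]
    return adata.X


def _counts_ok(counts) -> tuple[bool, bool]:
    """(non-negative, integral) for dense or sparse counts."""
    data = counts.data if sp.issparse(counts) else np.asarray(counts)
    if data.size == 0:
        return True, True
    nonneg = bool(data.min() >= 0)
    integral = bool(np.all(np.mod(data, 1) == 0))
    return nonneg, integral


def validate_dataset(
    adata: AnnData, config: SchemaConfig | None = None
) -> ValidationReport:
    """Validate one dataset against the minimal schema.

    Checks: presence and non-emptiness of the 11 required ``obs`` fields,
    CURIE syntax and configured prefix for ontology fields, the
    ``suspension_type`` vocabulary, a boolean ``is_primary_data``, a
    non-negative integral raw count matrix, unique gene identifiers, and at
    least one embedding with >= 2 dimensions. Side-effect free and
    idempotent; unknown extra ``obs`` columns are reported as ``info``.
    """
    config = config or SchemaConfig()
    report = ValidationReport()

    counts = get_counts(adata, config.counts_layer)
    if counts is None:
        report.add("error", "counts", "no raw count matrix found")
    else:
        nonneg, integral = _counts_ok(counts)
        if not nonneg:
            report.add("error", "counts", "negative count present")
        if not integral:
            report.add("error", "counts", "non-integral count present")

    if adata.var_names.has_duplicates:
        dups = adata.var_names[adata.var_names.duplicated()].unique().tolist()
        report.add("error", "genes", f"duplicate gene identifiers: {dups[:5]}")

    if not any(
        np.asarray(emb).ndim == 2 and np.asarray(emb).shape[1] >= 2
        for emb in adata.obsm.values()
    ):
        report.add("error", "embeddings", "no embedding with >= 2 dimensions")

    obs = adata.obs
    for f in config.required_fields:
        if f not in obs.columns:
            report.add("error", f"obs.{f}", f"required field '{f}' missing")
            continue
        col = obs[f]
        if f == "is_primary_data":
            if not (col.dtype == bool or set(col.unique()) <= {True, False}):
                report.add("error", f"obs.{f}", "is_primary_data must be boolean")
            continue
        empty = col.isna() | (col.astype(str).str.strip() == "")
        if empty.any():
            report.add(
                "error",
                f"obs.{f}",
                f"{int(empty.sum())} cells have empty '{f}'",
            )
            continue
        if f == "suspension_type":
            bad = set(col.unique()) - set(SUSPENSION_TYPES)
            if bad:
                report.add(
                    "error",
                    f"obs.{f}",
                    f"suspension_type values outside {SUSPENSION_TYPES}: {sorted(bad)}",
                )
            continue
        if f in config.prefixes:
            _check_curies(col, f, config.prefixes[f], report)

    if (
        config.ontology_terms is not None
        and "cell_type" in obs.columns
    ):
        unknown = sorted(set(obs["cell_type"].astype(str)) - set(config.ontology_terms))
        if unknown:
            report.add(
                "error",
                "obs.cell_type",
                f"cell_type terms not in supplied ontology: {unknown[:5]}",
            )

    extra = set(obs.columns) - set(config.required_fields) - {"cell_id"}
    for col in sorted(extra):
        report.add("info", f"obs.{col}", "extra metadata column (allowed)")

    return report


def _check_curies(
    col: pd.Series, name: str, prefixes: Sequence[str], report: ValidationReport
) -> None:
    values = col.astype(str)
    bad_syntax = ~values.map(lambda v: bool(CURIE_RE.match(v)))
    if bad_syntax.any():
        example = values[bad_syntax].iloc[0]
        report.add(
            "error",
            f"obs.{name}",
            f"{int(bad_syntax.sum())} values are not CURIEs (e.g. '{example}')",
        )
        return
    pfx = values.str.split(":").str[0]
    bad_prefix = ~pfx.isin(list(prefixes))
    if bad_prefix.any():
        example = values[bad_prefix].iloc[0]
        report.add(
            "error",
            f"obs.{name}",
            f"{int(bad_prefix.sum())} values outside prefixes {tuple(prefixes)} "
            f"(e.g. '{example}')",
        )


def cell_identifiers(adata: AnnData) -> pd.Series:
    """Stable cross-dataset cell identifier.

    Uses an explicit ``obs['cell_id']`` column when present; otherwise the
    dataset-local barcode combined with ``donor_id``, which curator
    bookkeeping keeps stable across submissions of the same material.
    """
    if "cell_id" in adata.obs.columns:
        return adata.obs["cell_id"].astype(str)
    donor = (
        adata.obs["donor_id"].astype(str)
        if "donor_id" in adata.obs.columns
        else pd.Series("", index=adata.obs_names)
    )
    return pd.Series(adata.obs_names.astype(str), index=adata.obs_names) + "|" + donor


def check_primary_uniqueness(datasets: Iterable[AnnData]) -> ValidationReport:
    """Verify each cell is flagged ``is_primary_data=True`` at most once.

    Duplicate submissions of the same material (e.g. a meta-analysis
    re-hosting original data) are permitted provided only one copy is primary, so
    corpus aggregations can exclude redundant observations.
    """
    report = ValidationReport()
    seen: dict[str, str] = {}
    for idx, adata in enumerate(datasets):
        name = adata.uns.get("dataset_id", f"dataset_{idx}")
        if "is_primary_data" not in adata.obs.columns:
            report.add("error", f"{name}.obs", "is_primary_data missing")
            continue
        ids = cell_identifiers(adata)
        primary = adata.obs["is_primary_data"].astype(bool).to_numpy()
        for cid in ids.to_numpy()[primary]:
            if cid in seen:
                report.add(
                    "error",
                    cid,
                    f"cell primary in both '{seen[cid]}' and '{name}'",
                )
            else:
                seen[cid] = name
    return report
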