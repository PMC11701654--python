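"""Computationally derived marker genes.

For a target cell type in a tissue, every gene is compared against each
other cell type in the same tissue with a two-sample t-test on the masked
normalized values (Welch's unequal-variance test by default; a pooled
Student variant mirrors validation studies). The per-comparison effect size
is the standardized mean difference d = (m_a - m_b) / sqrt((s_a^2 + s_b^2)/2).

A gene is a good marker when it separates the target from *nearly all* other
types, so the per-gene effects are collapsed to their 10th percentile. For
few comparisons that percentile is noisy; it is therefore bootstrapped —
resample the effect list with replacement, take each replicate's 10th
percentile, and average the replicates. The 25 genes with the largest
aggregated effects are returned.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .aggregate import CubePart

#: Finite stand-in for an infinite t / effect (zero variance, distinct means).
LARGE_SENTINEL = 1e6

TOP_K = 25
PERCENTILE = 10.0
DEFAULT_REPS = 100
MIN_CELLS = 5


@dataclass
class GroupStats:
    """Per-(cell type x gene) sufficient statistics of present values."""

    genes: np.ndarray  # sorted union of gene ids
    n: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    var: dict[str, np.ndarray]  # sample variance; NaN where n < 2

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.n)


# ------------------------------------------------------------------ tests


def _t_from_stats(na, ma, va, nb, mb, vb, variant: str):
    """Vectorized two-sample t, df and standardized effect from group stats."""
    diff = ma - mb
    if variant == "welch":
        sea = va / na
        seb = vb / nb
        se2 = sea + seb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(se2)
            df = se2**2 / (sea**2 / (na - 1) + seb**2 / (nb - 1))
            d = diff / np.sqrt((va + vb) / 2.0)
    elif variant == "student":
        df = na + nb - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            d = diff / np.sqrt(sp2)
    else:
        raise ValueError(f"unknown test variant: {variant!r}")
    # zero pooled variance: identical means -> 0; distinct means -> sentinel
    t = np.where(np.isnan(t) & (diff == 0), 0.0, t)
    d = np.where(np.isnan(d) & (diff == 0), 0.0, d)
    t = np.clip(np.nan_to_num(t, nan=np.nan, posinf=LARGE_SENTINEL, neginf=-LARGE_SENTINEL), -LARGE_SENTINEL, LARGE_SENTINEL)
    d = np.clip(np.nan_to_num(d, nan=np.nan, posinf=LARGE_SENTINEL, neginf=-LARGE_SENTINEL), -LARGE_SENTINEL, LARGE_SENTINEL)
    t = np.where(np.isnan(t) & (diff != 0), np.sign(diff) * LARGE_SENTINEL, t)
    d = np.where(np.isnan(d) & (diff != 0), np.sign(diff) * LARGE_SENTINEL, d)
    return t, df, d


def welch_t(group_a: Sequence[float], group_b: Sequence[float]):
    """Welch's t on two value vectors.

    Returns ``(t_stat, df, effect)`` where ``effect`` is the standardized
    mean difference with unpooled average variance. Each group needs at
    least 2 values. Zero-variance pairs with distinct means are guarded to a
    large finite sentinel rather than +/-inf.
    """
    return _t_pair(group_a, group_b, "welch")


def student_t(group_a: Sequence[float], group_b: Sequence[float]):
    """Student's pooled-variance t; effect is Cohen's d with pooled SD."""
    return _t_pair(group_a, group_b, "student")


def _t_pair(a, b, variant):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 present values")
    t, df, d = _t_from_stats(
        np.array([a.size]),
        np.array([a.mean()]),
        np.array([a.var(ddof=1)]),
        np.array([b.size]),
        np.array([b.mean()]),
        np.array([b.var(ddof=1)]),
        variant,
    )
    return float(t[0]), float(df[0]), float(d[0])


# -------------------------------------------------------------- bootstrap


def aggregate_effect(
    effects: Sequence[float],
    percentile: float = PERCENTILE,
    reps: int = DEFAULT_REPS,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Bootstrap-aggregated percentile of a gene's per-comparison effects.

    Draws ``reps`` resamples (with replacement, same size) of the effect
    list, takes the ``percentile``-th percentile of each (linear
    interpolation between order statistics), and returns the mean over
    replicates. Deterministic for a fixed generator/seed.
    """
    effects = np.asarray(effects, dtype=float)
    effects = effects[~np.isnan(effects)]
    if effects.size == 0:
        raise ValueError("no comparisons to aggregate")
    if effects.size == 1:
        return float(effects[0])
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, effects.size, size=(reps, effects.size))
    return float(np.mean(np.percentile(effects[idx], percentile, axis=1)))


# ------------------------------------------------------------ group stats


def tissue_group_stats(parts: Iterable[CubePart], tissue: str) -> GroupStats:
    """Sufficient statistics of present values per cell type, merged across
    datasets on the union of gene ids (a gene unmeasured by a dataset simply
    contributes no values for its cells)."""
    parts = list(parts)
    genes = sorted({g for p in parts for g in p.genes})
    gene_pos = {g: i for i, g in enumerate(genes)}
    acc: dict[str, list[np.ndarray]] = {}
    for part in parts:
        obs = part.metadata
        rows = np.flatnonzero((obs["tissue"].astype(str) == tissue).to_numpy())
        if rows.size == 0:
            continue
        values = (
            part.normalized.values
            if hasattr(part.normalized, "values")
            else sp.csr_matrix(part.normalized)
        )
        col_map = np.array([gene_pos[g] for g in part.genes])
        types = obs["cell_type"].astype(str).to_numpy()[rows]
        for ct in np.unique(types):
            sub = values[rows[types == ct]]
            ones = sub.copy()
            ones.data = np.ones_like(ones.data)
            sq = sub.copy()
            sq.data = sq.data**2
            n_local = np.asarray(ones.sum(axis=0)).ravel()
            s1_local = np.asarray(sub.sum(axis=0)).ravel()
            s2_local = np.asarray(sq.sum(axis=0)).ravel()
            if ct not in acc:
                acc[ct] = [np.zeros(len(genes)) for _ in range(3)]
            n, s1, s2 = acc[ct]
            np.add.at(n, col_map, n_local)
            np.add.at(s1, col_map, s1_local)
            np.add.at(s2, col_map, s2_local)
    n_d, m_d, v_d = {}, {}, {}
    for ct, (n, s1, s2) in acc.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
            var = np.where(
                n > 1, np.maximum(s2 - n * mean**2, 0.0) / np.maximum(n - 1, 1), np.nan
            )
        n_d[ct], m_d[ct], v_d[ct] = n, mean, var
    return GroupStats(genes=np.array(genes, dtype=object), n=n_d, mean=m_d, var=v_d)


# --------------------------------------------------------------- top-25


def compute_markers(
    stats: GroupStats,
    tissue: str,
    target_type: str,
    k: int = TOP_K,
    percentile: float = PERCENTILE,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    min_cells: int = MIN_CELLS,
    variant: str = "welch",
    effect_metric: str = "smd",
) -> pd.DataFrame:
    """Top-k marker genes for one (tissue, cell type).

    Per gene, effect sizes against every other cell type in the tissue are
    aggregated by bootstrapped 10th percentile; genes rank by aggregated
    effect, ties broken by gene id, and the top ``k`` are returned as rows
    (tissue, cell_type, rank, gene, effect). Comparisons where either group
    has fewer than ``min_cells`` present values are skipped; genes with no
    usable comparison are excluded. A tissue with a single cell type yields
    an empty table.
    """
    others = [ct for ct in stats.cell_types if ct != target_type]
    if target_type not in stats.n:
        raise KeyError(f"cell type {target_type!r} not present in tissue {tissue!r}")
    if not others:
        return pd.DataFrame(columns=["tissue", "cell_type", "rank", "gene", "effect"])

    na, ma, va = stats.n[target_type], stats.mean[target_type], stats.var[target_type]
    effect_cols = []
    for other in others:
        nb, mb, vb = stats.n[other], stats.mean[other], stats.var[other]
        usable = (na >= min_cells) & (nb >= min_cells)
        t, _, d = _t_from_stats(
            np.maximum(na, 2), ma, va, np.maximum(nb, 2), mb, vb, variant
        )
        eff = t if effect_metric == "t" else d
        effect_cols.append(np.where(usable, eff, np.nan))
    effects = np.column_stack(effect_cols)  # genes x comparisons

    records = []
    for gi, gene in enumerate(stats.genes):
        row = effects[gi]
        row = row[~np.isnan(row)]
        if row.size == 0:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [seed, zlib.crc32(f"{tissue}|{target_type}|{gene}".encode())]
            )
        )
        agg = aggregate_effect(row, percentile=percentile, reps=reps, rng=rng)
        records.append((gene, agg))
    if not records:
        return pd.DataFrame(columns=["tissue", "cell_type", "rank", "gene", "effect"])
    table = pd.DataFrame(records, columns=["gene", "effect"])
    table = table.sort_values(
        ["effect", "gene"], ascending=[False, True], kind="mergesort"
    ).head(k)
    table.insert(0, "cell_type", target_type)
    table.insert(0, "tissue", tissue)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["tissue", "cell_type", "rank", "gene", "effect"]].reset_index(
        drop=True
    )


def compute_markers_student(*args, **kwargs) -> pd.DataFrame:
    """Marker derivation with Student's pooled-variance t (validation arm)."""
    kwargs["variant"] = "student"
    return compute_markers(*args, **kwargs)


def compute_markers_all(
    parts: Iterable[CubePart],
    k: int = TOP_K,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    variant: str = "welch",
    **kwargs,
) -> pd.DataFrame:
    """Marker tables for every (tissue, cell type) in the corpus."""
    parts = list(parts)
    tissues = sorted(
        {t for p in parts for t in p.metadata["tissue"].astype(str).unique()}
    )
    frames = []
    for tissue in tissues:
        stats = tissue_group_stats(parts, tissue)
        for ct in stats.cell_types:
            frames.append(
                compute_markers(
                    stats, tissue, ct, k=k, reps=reps, seed=seed, variant=variant,
                    **kwargs,
                )
            )
    if not frames:
        return pd.DataFrame(columns=["tissue", "cell_type", "rank", "gene", "effect"])
    return pd.concat(frames, ignore_index=True)
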