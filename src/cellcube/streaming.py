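"""Out-of-core statistics over chunked corpora.

Corpus-scale matrices do not fit in memory, so per-gene means and variances
are computed in a single pass over fixed-size chunks of cells using
Welford's online algorithm in its batched (parallel) form: each chunk's
mean and sum of squared deviations are combined into the running state with
Chan's update, and states from disjoint passes merge associatively so
computation can be sharded.

For numerical stability on ill-conditioned data (large mean, tiny variance)
the state keeps a per-gene shift anchored at the first chunk's means and
accumulates in shifted coordinates: subtracting a nearby constant is exact
in floating point, so the running quantities stay at the scale of the
spread rather than the mean.

Highly variable genes are ranked by the variance of their normalized values
across all cells; the ranking is invariant to the chunk size used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp


@dataclass
class StreamStat:
    """Mergeable running mean/variance state, one entry per gene.

    ``mean`` is stored relative to ``shift``; the true mean is
    ``shift + mean``. ``M2`` (the running sum of squared deviations) is
    shift-invariant.
    """

    n: np.ndarray  # observation count per gene
    mean: np.ndarray  # shifted running mean
    M2: np.ndarray
    shift: np.ndarray

    @classmethod
    def empty(cls, n_genes: int) -> "StreamStat":
        return cls(
            n=np.zeros(n_genes, dtype=np.int64),
            mean=np.zeros(n_genes),
            M2=np.zeros(n_genes),
            shift=np.zeros(n_genes),
        )

    @property
    def n_genes(self) -> int:
        return self.mean.shape[0]

    def finalize(self, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mean, variance, defined) per gene.

        ``variance`` is the sample (n-1) variance by default; pass
        ``ddof=0`` for the population variance. Genes with fewer than
        ``ddof + 1`` observations have undefined variance: NaN with
        ``defined=False``.
        """
        denom = self.n - ddof
        defined = denom > 0
        var = np.full(self.n_genes, np.nan)
        var[defined] = self.M2[defined] / denom[defined]
        mean = np.where(self.n > 0, self.shift + self.mean, np.nan)
        return mean, var, defined


def _chunk_dense(chunk) -> np.ndarray:
    if hasattr(chunk, "submatrix"):  # an io.Chunk
        chunk = chunk.submatrix
    if sp.issparse(chunk):
        return np.asarray(chunk.todense(), dtype=float)
    return np.atleast_2d(np.asarray(chunk, dtype=float))


def welford_update(state: StreamStat, chunk_values) -> StreamStat:
    """Fold one chunk (cells x genes) into the running state, in place.

    Every matrix entry counts as an observation (zeros included). Memory use
    is bounded by the chunk itself plus the O(genes) state.
    """
    block = _chunk_dense(chunk_values)
    if block.size == 0 or block.shape[0] == 0:
        return state
    if block.shape[1] != state.n_genes:
        raise ValueError(
            f"chunk has {block.shape[1]} genes, state has {state.n_genes}"
        )
    if not state.n.any():
        state.shift = block.mean(axis=0)
    shifted = block - state.shift
    m = block.shape[0]
    b_mean = shifted.mean(axis=0)
    b_M2 = ((shifted - b_mean) ** 2).sum(axis=0)
    _combine(state, m, b_mean, b_M2)
    return state


def _combine(state: StreamStat, m, b_mean: np.ndarray, b_M2: np.ndarray) -> None:
    """Chan's parallel combination in the state's shifted coordinates."""
    n = state.n
    total = n + m
    delta = b_mean - state.mean
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.maximum(total, 1)
        state.M2 = state.M2 + b_M2 + delta**2 * (n * m / safe)
        state.mean = np.where(total > 0, state.mean + delta * (m / safe), state.mean)
    state.n = total


def merge_states(a: StreamStat, b: StreamStat) -> StreamStat:
    """Combine two states as if their data had been processed sequentially.

    ``b``'s running mean is rebased onto ``a``'s shift (exact for nearby
    anchors) before Chan's combination; agreement with sequential processing
    is within floating tolerance.
    """
    if a.n_genes != b.n_genes:
        raise ValueError("states cover different gene axes")
    if not a.n.any():
        return StreamStat(b.n.copy(), b.mean.copy(), b.M2.copy(), b.shift.copy())
    out = StreamStat(a.n.copy(), a.mean.copy(), a.M2.copy(), a.shift.copy())
    if not b.n.any():
        return out
    b_mean_rebased = (b.shift - out.shift) + b.mean
    _combine(out, b.n, b_mean_rebased, b.M2)
    return out


def stream_stats(chunks: Iterable, n_genes: int | None = None) -> StreamStat:
    """Run Welford over an iterator of chunks."""
    state: StreamStat | None = None
    for chunk in chunks:
        block = _chunk_dense(chunk)
        if state is None:
            state = StreamStat.empty(block.shape[1])
        welford_update(state, block)
    if state is None:
        if n_genes is None:
            raise ValueError("empty stream and no gene count given")
        state = StreamStat.empty(n_genes)
    return state


def hvg_streaming(
    chunks: Iterable,
    n_top: int,
    gene_names: Sequence[str] | None = None,
    method: str = "variance",
) -> list:
    """Top ``n_top`` highly variable genes from a chunk stream.

    Genes are ranked by the sample variance of their values across all cells
    (default), or by dispersion (variance / mean) with
    ``method="dispersion"``. Undefined scores rank last; ties break by gene
    order for determinism. The result does not depend on the chunk size.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    state = stream_stats(chunks)
    mean, var, _defined = state.finalize(ddof=1)
    if method == "variance":
        score = var
    elif method == "dispersion":
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(mean > 0, var / mean, np.nan)
    else:
        raise ValueError(f"unknown HVG method: {method!r}")
    score = np.where(np.isnan(score), -np.inf, score)
    order = np.lexsort((np.arange(state.n_genes), -score))
    top = order[: min(n_top, state.n_genes)]
    if gene_names is not None:
        names = np.asarray(gene_names, dtype=object)
        return list(names[top])
    return list(top)
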