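"""Out-of-core mean/variance and highly variable genes over chunked data.

Streams a dataset in fixed-size chunks through Welford's online algorithm
and shows that the result matches an in-memory two-pass computation and
does not depend on the chunk size.
"""

import numpy as np

from cellcube.io import iter_chunks
from cellcube.preprocess import run_preprocess
from cellcube.streaming import hvg_streaming, stream_stats
from cellcube.synth import SynthConfig, generate_corpus

corpus = generate_corpus(SynthConfig(seed=0, cells_per_type=40, n_genes=600))
adata = corpus.datasets[0]
res = run_preprocess([adata])["dataset_0"]
values = res.normalized.values
genes = list(adata.var_names)

dense = np.asarray(values.todense())
for chunk_size in (7, 64, 100_000):
    chunks = (values[i:i + chunk_size] for i in range(0, values.shape[0], chunk_size))
    state = stream_stats(chunks)
    mean, var, _ = state.finalize()
    err = np.nanmax(np.abs(var - dense.var(axis=0, ddof=1)))
    print(f"chunk_size {chunk_size:>6}: max |streamed - in-memory| variance "
          f"difference = {err:.2e}")

top = hvg_streaming(
    (c.submatrix for c in iter_chunks(adata, 64)), n_top=5, gene_names=genes
)
print("top 5 highly variable genes (raw counts):", top)
# the streamed state never holds more than one chunk plus O(genes) numbers,
# so the same code scales to corpora far larger than memory.
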