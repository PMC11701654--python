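"""Build the corpus expression cube and roll it up the cell-type ontology.

The cube holds, per (tissue, cell type, gene): the mean of present
(unmasked, non-zero) normalized values, the number of expressing cells and
the stratum size. Rolling up attributes each annotated term's sums to every
ancestor, so coarse terms like "lymphocyte" summarize their descendants.
"""

from cellcube.aggregate import CubePart, build_cube, cube_rollup
from cellcube.preprocess import run_preprocess
from cellcube.synth import SynthConfig, generate_corpus

corpus = generate_corpus(SynthConfig(seed=0, cells_per_type=40, n_genes=600))
results = run_preprocess(corpus.datasets)
parts = [
    CubePart(r.normalized, d.obs.iloc[r.retained], list(d.var_names))
    for d, r in zip(corpus.datasets, results.values())
]

cube = build_cube(parts)
print(f"cube: {len(cube)} (tissue, cell type, gene) rows")
print(cube.head(3).to_string(index=False))

rolled = cube_rollup(cube, corpus.graph)
lymph = rolled[rolled.cell_type == "CL:0000542"]
b_cell = cube[cube.cell_type == "CL:0000236"]
print(f"\nannotated B-cell stratum: {b_cell['n_cells'].iloc[0]} cells")
print(f"rolled-up lymphocyte stratum: {lymph['n_cells'].iloc[0]} cells "
      "(B + plasma + T + coarse-labeled lymphocytes)")

# A faceted cube stratifies every key by extra metadata, here donor sex:
by_sex = build_cube(parts, group_by=["sex"])
print(f"\nwith group_by=['sex']: {len(by_sex)} rows "
      f"({by_sex['sex'].nunique()} strata per cell type)")
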