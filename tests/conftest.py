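import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from cellcube.aggregate import CubePart
from cellcube.preprocess import run_preprocess
from cellcube.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A scaled-down seeded corpus shared across unit tests."""
    return generate_corpus(SynthConfig(seed=11, cells_per_type=30, n_genes=600))


@pytest.fixture(scope="session")
def small_results(small_corpus):
    return run_preprocess(small_corpus.datasets)


@pytest.fixture(scope="session")
def small_parts(small_corpus, small_results):
    return [
        CubePart(
            normalized=res.normalized,
            metadata=d.obs.iloc[res.retained],
            genes=list(d.var_names),
        )
        for d, res in zip(small_corpus.datasets, small_results.values())
    ]


def make_adata(counts, cell_types=None, tissue="UBERON:0002048", **obs_overrides):
    """Hand-built schema-conformant dataset for targeted tests."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "organism": "NCBITaxon:9606",
            "tissue": tissue,
            "cell_type": cell_types if cell_types is not None else "CL:0000236",
            "assay": "EFO:0009899",
            "disease": "PATO:0000461",
            "sex": "PATO:0000383",
            "self_reported_ethnicity": "HANCESTRO:0005",
            "development_stage": "HsapDv:0000087",
            "donor_id": "donor_0",
            "suspension_type": "cell",
            "is_primary_data": True,
        },
        index=[f"cell{i}" for i in range(n)],
    )
    for key, val in obs_overrides.items():
        obs[key] = val
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )
    adata.obsm["X_umap"] = np.zeros((n, 2))
    return adata
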