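import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import norm

from cellcube.preprocess import (
    ASSAY_ALLOWLIST,
    NormalizedMatrix,
    PreprocessConfig,
    dedup_primary,
    filter_assay,
    filter_low_coverage,
    mask_low_expression,
    normalize_cptt,
    normalize_quantile,
    run_preprocess,
)


class TestFilters:
    def test_dedup_keeps_only_primary(self):
        obs = pd.DataFrame({"is_primary_data": [True, False, True, True, False]})
        assert dedup_primary(obs).tolist() == [0, 2, 3]
        assert dedup_primary(pd.DataFrame({"is_primary_data": [False] * 3})).size == 0
        assert dedup_primary(pd.DataFrame({"is_primary_data": [True] * 3})).tolist() == [0, 1, 2]

    def test_low_coverage_boundary(self):
        # three cells: 499, 500 and 0 expressed genes out of 600
        counts = np.zeros((3, 600), dtype=int)
        counts[0, :499] = 1
        counts[1, :500] = 1
        kept = filter_low_coverage(counts, min_genes=500)
        assert kept.tolist() == [1]

    def test_allowlist_contains_table_assays(self):
        assert "EFO:0009899" in ASSAY_ALLOWLIST  # 10x 3' v2
        assert "EFO:0008722" in ASSAY_ALLOWLIST  # Drop-seq
        assert len(ASSAY_ALLOWLIST) == 12

    def test_assay_filter_semantics(self):
        obs = pd.DataFrame(
            {"assay": ["EFO:0009899", "EFO:0008722", "EFO:9999999", "EFO:0008931"]}
        )
        assert filter_assay(obs).tolist() == [0, 1]
        with pytest.raises(ValueError):
            filter_assay(obs, frozenset())


class TestNormalizeCptt:
    def test_closed_form_values(self):
        row = np.zeros((1, 10_000))
        row[0, 0] = 1  # total 10 000 after filling rest
        row[0, 1:] = 1
        # simpler targeted cases:
        counts = np.array([[0, 1, 9_999]])  # total 10 000
        out = np.asarray(normalize_cptt(counts).todense())
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(np.log(2.0), rel=1e-12)
        counts = np.array([[10, 4_990]])  # total 5 000
        out = np.asarray(normalize_cptt(counts).todense())
        assert out[0, 0] == pytest.approx(np.log(21.0), rel=1e-12)

    def test_cptt_conservation_before_log(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(5, 40))
        counts[:, 0] += 1  # positive totals
        out = np.asarray(normalize_cptt(counts).todense())
        cptt_sums = np.expm1(out).sum(axis=1)
        np.testing.assert_allclose(cptt_sums, 10_000.0, rtol=1e-9)

    def test_monotone_in_count_at_fixed_total(self):
        counts = np.array([[1, 2, 3, 4, 10]])
        out = np.asarray(normalize_cptt(counts).todense()).ravel()
        assert np.all(np.diff(out) > 0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_cptt(np.zeros((1, 3)))


class TestNormalizeQuantile:
    def test_single_nonzero_maps_to_median_quantile(self):
        out = np.asarray(normalize_quantile(np.array([[0, 5, 0]])).todense())
        assert out[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_nonzero_symmetric(self):
        out = np.asarray(normalize_quantile(np.array([[3, 9]])).todense()).ravel()
        expected = norm.ppf([0.25, 0.75])
        np.testing.assert_allclose(np.sort(out), expected, rtol=1e-12)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        row = rng.integers(1, 100, size=(1, 30))
        out = np.asarray(normalize_quantile(row).todense()).ravel()
        assert np.array_equal(np.argsort(row.ravel(), kind="stable"),
                              np.argsort(out, kind="stable"))


class TestMask:
    def _norm(self, values):
        return NormalizedMatrix(values=sp.csr_matrix(values))

    def test_boundary_at_threshold(self):
        masked = mask_low_expression(self._norm([[3.0, 3.01, 5.0]]))
        dense = np.asarray(masked.values.todense())
        assert dense[0, 0] == 0.0  # exactly 3 -> missing
        assert dense[0, 1] == 3.01
        assert masked.values.nnz == 2

    def test_idempotent(self):
        once = mask_low_expression(self._norm([[1.0, 4.0, 2.9]]))
        twice = mask_low_expression(once)
        assert (once.values != twice.values).nnz == 0
        assert once.provenance == twice.provenance

    def test_raw_scale_variant(self):
        raw = np.array([[3, 4, 0]])
        values = normalize_cptt(raw)
        masked = mask_low_expression(
            NormalizedMatrix(values=values), raw_counts=raw, scale="raw"
        )
        dense = np.asarray(masked.values.todense())
        assert dense[0, 0] == 0.0  # raw count 3 -> masked
        assert dense[0, 1] > 0.0  # raw count 4 survives


class TestPipeline:
    def test_planted_cells_removed_exactly(self, small_corpus, small_results):
        removals = small_corpus.planted_removals
        reason_of_stage = {
            "dedup_primary": "nonprimary",
            "filter_low_coverage": "low_coverage",
            "filter_assay": "bad_assay",
        }
        for adata in small_corpus.datasets:
            ds = adata.uns["dataset_id"]
            res = small_results[ds]
            planted = removals[removals.dataset_id == ds]
            for stage, reason in reason_of_stage.items():
                assert res.removed[stage] == (planted.reason == reason).sum()
            kept_barcodes = set(adata.obs_names[res.retained])
            assert kept_barcodes.isdisjoint(set(planted.barcode))
            assert len(kept_barcodes) == adata.n_obs - len(planted)

    def test_post_mask_values_exceed_threshold(self, small_results):
        for res in small_results.values():
            data = res.normalized.values.data
            assert data.size and np.all(data > 3.0)

    def test_disabling_all_filters_normalizes_everyone(self, small_corpus):
        cfg = PreprocessConfig(
            do_dedup=False, do_low_coverage=False, do_assay=False, do_mask=False
        )
        adata = small_corpus.datasets[0]
        res = run_preprocess([adata], cfg)["dataset_0"]
        assert len(res.retained) == adata.n_obs
        assert res.normalized.values.shape[0] == adata.n_obs

    def test_provenance_lists_steps_in_order(self, small_results):
        prov = next(iter(small_results.values())).normalized.provenance
        names = [p.split("(")[0] for p in prov]
        assert names == [
            "dedup_primary",
            "filter_low_coverage",
            "filter_assay",
            "normalize_cptt",
            "mask_low_expression",
        ]

    def test_dataset_order_immaterial(self, small_corpus):
        fwd = run_preprocess(small_corpus.datasets)
        rev = run_preprocess(list(reversed(small_corpus.datasets)))
        for name in fwd:
            assert (fwd[name].normalized.values != rev[name].normalized.values).nnz == 0
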