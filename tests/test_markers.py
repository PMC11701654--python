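import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as ss

from cellcube.aggregate import CubePart
from cellcube.markers import (
    LARGE_SENTINEL,
    aggregate_effect,
    compute_markers,
    compute_markers_all,
    compute_markers_student,
    student_t,
    tissue_group_stats,
    welch_t,
)
from cellcube.preprocess import NormalizedMatrix

from test_aggregate import part  # hand-built CubePart helper


class TestWelch:
    def test_identical_groups_give_zero(self):
        t, df, d = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and d == 0.0

    def test_printed_toy_vectors_match_closed_form(self):
        t, df, d = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert df == pytest.approx(4.0, rel=1e-12)
        assert d == pytest.approx(-3.0, rel=1e-12)
        ref = ss.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)

    def test_agrees_with_reference_routine_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 20))
            b = rng.normal(1, 2, size=rng.integers(3, 20))
            t, df, _ = welch_t(a, b)
            ref = ss.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            ts, dfs, _ = student_t(a, b)
            refs = ss.ttest_ind(a, b, equal_var=True)
            assert ts == pytest.approx(refs.statistic, rel=1e-10)
            assert dfs == len(a) + len(b) - 2

    def test_zero_variance_distinct_means_guarded_to_sentinel(self):
        t, _, d = welch_t([1.0, 1.0], [2.0, 2.0])
        assert t == -LARGE_SENTINEL and d == -LARGE_SENTINEL

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_student_equals_welch_for_equal_variances(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        b = rng.normal(1.0, 1.0, size=30)
        _, _, dw = welch_t(a, b)
        _, _, dst = student_t(a, b)
        assert dw == pytest.approx(dst, rel=0.05)


class TestAggregateEffect:
    def test_single_comparison_passes_through(self):
        assert aggregate_effect([2.5]) == 2.5

    def test_constant_list_is_constant(self):
        assert aggregate_effect([1.7] * 8, reps=50, rng=3) == pytest.approx(1.7)

    def test_matches_independent_bootstrap_expectation(self):
        """Mean replicate 10th percentile of [0..9] vs a brute-force
        simulation with an independent generator."""
        effects = np.arange(10.0)
        got = aggregate_effect(effects, reps=10_000, rng=123)
        rng = np.random.default_rng(999)
        reps = rng.integers(0, 10, size=(20_000, 10))
        expected = np.percentile(effects[reps], 10.0, axis=1).mean()
        assert got == pytest.approx(expected, abs=0.05)

    def test_deterministic_given_seed(self):
        e = list(np.random.default_rng(0).normal(size=6))
        assert aggregate_effect(e, rng=7) == aggregate_effect(e, rng=7)
        assert aggregate_effect(e, rng=7) != aggregate_effect(e, rng=8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_effect([])


def two_type_parts(rng=None, shift=0.0, scale=1.0):
    rng = rng or np.random.default_rng(5)
    a = np.abs(rng.normal(8, 1, size=(20, 6))) + 4
    b = np.abs(rng.normal(5, 1, size=(20, 6))) + 4
    a[:, 0] += 6  # gene g0 marks type A
    values = np.vstack([a, b]) * scale
    values[:, 1] += shift
    return part(values, ["CL:A"] * 20 + ["CL:B"] * 20, [f"g{i}" for i in range(6)])


class TestComputeMarkers:
    def test_two_type_tissue_ranking_equals_single_comparison(self):
        p = two_type_parts()
        stats = tissue_group_stats([p], "UBERON:0002048")
        table = compute_markers(stats, "UBERON:0002048", "CL:A", seed=1)
        assert table.iloc[0]["gene"] == "g0"
        assert table["effect"].is_monotonic_decreasing
        # one comparison only: aggregated effect equals the pairwise effect
        dense = np.asarray(p.normalized.values.todense())
        types = p.metadata["cell_type"].to_numpy()
        for _, row in table.iterrows():
            gi = list(stats.genes).index(row["gene"])
            a = dense[types == "CL:A", gi]
            b = dense[types == "CL:B", gi]
            _, _, d = welch_t(a[a != 0], b[b != 0])
            assert row["effect"] == pytest.approx(d, rel=1e-12)

    def test_k_cap_and_singleton_tissue(self):
        p = two_type_parts()
        stats = tissue_group_stats([p], "UBERON:0002048")
        table = compute_markers(stats, "UBERON:0002048", "CL:A", k=25, seed=0)
        assert len(table) <= 6  # only 6 genes exist
        solo = part(np.full((5, 3), 5.0), ["CL:A"] * 5, ["g0", "g1", "g2"])
        stats_solo = tissue_group_stats([solo], "UBERON:0002048")
        assert compute_markers(stats_solo, "UBERON:0002048", "CL:A", seed=0).empty

    def test_translation_and_scale_invariance(self):
        base = tissue_group_stats([two_type_parts()], "UBERON:0002048")
        shifted = tissue_group_stats([two_type_parts(shift=5.0)], "UBERON:0002048")
        scaled = tissue_group_stats([two_type_parts(scale=3.0)], "UBERON:0002048")
        t0 = compute_markers(base, "UBERON:0002048", "CL:A", seed=4)
        t1 = compute_markers(shifted, "UBERON:0002048", "CL:A", seed=4)
        t2 = compute_markers(scaled, "UBERON:0002048", "CL:A", seed=4)
        pd.testing.assert_series_equal(t0["effect"], t1["effect"], rtol=1e-9)
        pd.testing.assert_series_equal(t0["effect"], t2["effect"], rtol=1e-9)
        assert t0["gene"].tolist() == t1["gene"].tolist() == t2["gene"].tolist()

    def test_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(9)
        p = two_type_parts()
        perm = rng.permutation(p.normalized.values.shape[0])
        shuffled = CubePart(
            normalized=NormalizedMatrix(values=p.normalized.values[perm]),
            metadata=p.metadata.iloc[perm].reset_index(drop=True),
            genes=p.genes,
        )
        a = compute_markers(
            tissue_group_stats([p], "UBERON:0002048"), "UBERON:0002048", "CL:A", seed=2
        )
        b = compute_markers(
            tissue_group_stats([shuffled], "UBERON:0002048"),
            "UBERON:0002048",
            "CL:A",
            seed=2,
        )
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("runner", [compute_markers_all])
    def test_planted_markers_recovered(self, small_corpus, small_parts, runner):
        table = runner(small_parts, seed=11)
        for (tissue, ct), grp in small_corpus.true_markers.groupby(
            ["tissue", "cell_type"]
        ):
            predicted = set(
                table[(table.tissue == tissue) & (table.cell_type == ct)]["gene"]
            )
            assert set(grp["gene"]) <= predicted

    def test_student_variant_also_recovers(self, small_corpus, small_parts):
        stats = tissue_group_stats(small_parts, "UBERON:0002048")
        truth = small_corpus.true_markers
        ct = truth["cell_type"].iloc[0]
        table = compute_markers_student(
            stats, "UBERON:0002048", ct, seed=11
        )
        planted = set(truth[truth.cell_type == ct]["gene"])
        assert planted <= set(table["gene"])
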