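import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from cellcube.synth import SynthConfig, generate_corpus, generate_reference_markers
from cellcube.validation import (
    batch_effect_study,
    marker_recall,
    recall_study,
    rm_anova,
)


def enumerate_overlap_tail(universe, n_ref, n_pred, k):
    """Exhaustive oracle: P[overlap >= k] over all C(universe, n_pred) draws."""
    ref = set(range(n_ref))
    hits = total = 0
    for draw in itertools.combinations(range(universe), n_pred):
        total += 1
        hits += len(ref & set(draw)) >= k
    return hits / total


class TestMarkerRecall:
    def test_perfect_and_disjoint_cases(self):
        r = marker_recall({"a", "b"}, {"a", "b"}, universe_size=10)
        assert r.recall == 1.0
        r = marker_recall({"a"}, {"b"}, universe_size=10)
        assert r.recall == 0.0
        assert r.p_chance == pytest.approx(1.0)

    def test_worked_example_matches_enumeration(self):
        """universe 10, reference 4, predicted 5, overlap 3."""
        predicted = {"r0", "r1", "r2", "x0", "x1"}
        reference = {"r0", "r1", "r2", "r3"}
        r = marker_recall(predicted, reference, universe_size=10)
        assert r.n_overlap == 3
        expected = enumerate_overlap_tail(10, 4, 5, 3)
        assert r.p_chance == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(66 / 252)

    @pytest.mark.parametrize("universe,n_ref,n_pred", [(8, 3, 4), (12, 5, 6), (15, 4, 7)])
    def test_tail_matches_enumeration_small_universes(self, universe, n_ref, n_pred):
        for k in range(0, min(n_ref, n_pred) + 1):
            predicted = {f"r{i}" for i in range(k)} | {
                f"x{i}" for i in range(n_pred - k)
            }
            reference = {f"r{i}" for i in range(n_ref)}
            r = marker_recall(predicted, reference, universe)
            assert r.p_chance == pytest.approx(
                enumerate_overlap_tail(universe, n_ref, n_pred, k), rel=1e-10
            )

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            marker_recall({"a"}, set(), 10)


class TestRecallStudy:
    def test_clean_reference_gives_full_recall(self, small_corpus, small_parts):
        ref = generate_reference_markers(small_corpus)
        table = recall_study(small_parts, ref, small_corpus.graph, seed=11)
        assert len(table) > 0
        assert table["recall"].mean() == pytest.approx(1.0)
        assert (table["p_chance"] < 0.05).all()

    def test_half_noise_gives_half_recall(self, small_corpus, small_parts):
        ref = generate_reference_markers(small_corpus, noise=0.5, seed=2)
        table = recall_study(small_parts, ref, small_corpus.graph, seed=11)
        assert table["recall"].mean() == pytest.approx(0.5, abs=0.15)

    def test_colinear_reference_types_pruned(self, small_corpus, small_parts):
        ref = generate_reference_markers(small_corpus)
        # B cell (CL:0000236) is an ancestor of plasma cell (CL:0000786):
        # both appear in the reference, only the descendant is evaluated
        evaluated = set(
            recall_study(small_parts, ref, small_corpus.graph, seed=11)["cell_type"]
        )
        assert "CL:0000786" in evaluated
        assert "CL:0000236" not in evaluated


class TestRmAnova:
    def test_no_effect_gives_f_zero_p_one(self):
        table = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2", "g2"],
                "covariate_level": ["a", "b", "a", "b"],
                "avg_expression": [1.0, 1.0, 2.0, 2.0],
            }
        )
        res = rm_anova(table)
        assert res.F == 0.0 and res.p == 1.0

    def test_two_level_case_equals_paired_t_squared(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(6)]
        a = rng.normal(5, 1, size=6)
        b = a + 0.8 + rng.normal(0, 0.3, size=6)
        table = pd.DataFrame(
            {
                "gene": genes * 2,
                "covariate_level": ["a"] * 6 + ["b"] * 6,
                "avg_expression": np.concatenate([a, b]),
            }
        )
        res = rm_anova(table)
        t = ss.ttest_rel(a, b)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_textbook_table_matches_hand_sums_of_squares(self):
        # 5 subjects x 3 conditions; oracle computed from the classical
        # within-subject decomposition below, independent of the implementation
        data = np.array(
            [
                [45.0, 50.0, 55.0],
                [42.0, 42.0, 45.0],
                [36.0, 41.0, 43.0],
                [39.0, 35.0, 40.0],
                [51.0, 55.0, 59.0],
            ]
        )
        n, k = data.shape
        grand = data.mean()
        ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((data - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        f_expected = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        table = pd.DataFrame(
            {
                "gene": np.repeat([f"s{i}" for i in range(n)], k),
                "covariate_level": ["c1", "c2", "c3"] * n,
                "avg_expression": data.ravel(),
            }
        )
        res = rm_anova(table)
        assert res.F == pytest.approx(f_expected, rel=1e-9)

    def test_unbalanced_design_drops_incomplete_genes(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2", "g2", "g3"],  # g3 misses level b
                "covariate_level": ["a", "b", "a", "b", "a"],
                "avg_expression": rng.normal(size=5),
            }
        )
        res = rm_anova(table)
        assert np.isfinite(res.F)

    def test_single_level_rejected(self):
        table = pd.DataFrame(
            {
                "gene": ["g1", "g2"],
                "covariate_level": ["a", "a"],
                "avg_expression": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            rm_anova(table)


@pytest.fixture(scope="module")
def shifted_corpus():
    return generate_corpus(
        SynthConfig(seed=21, cells_per_type=30, n_genes=600, batch_effect=0.6)
    )


@pytest.fixture(scope="module")
def gene_sets(shifted_corpus):
    markers = sorted(shifted_corpus.true_markers["gene"].unique())
    background = [
        f"gene_{i:04d}" for i in range(40) if f"gene_{i:04d}" not in set(markers)
    ][:25]
    return {"markers": markers, "housekeeping": background}


class TestBatchEffectStudy:
    def test_log_normalization_mitigates_depth_shifts(self, shifted_corpus, gene_sets):
        raw = batch_effect_study(
            shifted_corpus.datasets, "dataset_id", "raw", gene_sets
        )
        logn = batch_effect_study(
            shifted_corpus.datasets, "dataset_id", "cptt_log", gene_sets
        )
        assert raw["p"].median() < logn["p"].median()

    def test_single_gene_yields_no_row_and_covariate_guard(self, shifted_corpus):
        with pytest.raises(ValueError, match="constant"):
            batch_effect_study(
                shifted_corpus.datasets[:1], "dataset_id", "raw", {"s": ["gene_0000"]}
            )

    def test_assay_covariate_runs(self, shifted_corpus, gene_sets):
        table = batch_effect_study(
            shifted_corpus.datasets, "assay", "cptt_log", gene_sets
        )
        assert set(table["covariate"]) == {"assay"}
        assert ((table["F"] >= 0) & (table["p"] <= 1)).all()
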