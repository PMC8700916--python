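import numpy as np
import pytest

from omicsmkl import (
    BlockConfig,
    CVConfig,
    SyntheticConfig,
    composition_summary,
    final_feature_set,
    generate_multiomics,
    make_folds,
    mrmr_rank,
    nested_cv_evaluate,
    roc_auc,
    run_experiment_suite,
    wrapper_select_n,
)
from omicsmkl.dataset import FeatureRef

from oracles import auc_pair_count


def _fast_fixture(seed=0, n=60):
    """Two small blocks, strong signal in the first; cheap to cross-validate."""
    cfg = SyntheticConfig(
        n_samples=n, prevalence_positive=0.4,
        blocks=[
            BlockConfig("S", "continuous", 25, n_informative=6, effect_size=2.0),
            BlockConfig("N", "continuous", 15),
        ],
        seed=seed,
    )
    return generate_multiomics(cfg)[0]


FAST_CV = dict(outer_folds=3, inner_folds=3, n_grid=(5, 10, 20), stratified=True)


class TestRocAuc:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1], 1.0),   # perfect ranking
        ([0.5, 0.5], [1, -1], 0.5),                     # all ties
        ([0.9, 0.4, 0.6, 0.1], [1, -1, 1, -1], 1.0),
        ([0.9, 0.4, 0.6, 0.1], [-1, 1, -1, 1], 0.0),    # inverted labels
    ])
    def test_hand_examples(self, scores, labels, expected):
        auc, points = roc_auc(np.array(scores), np.array(labels))
        assert auc == expected
        assert points.shape[1] == 2

    def test_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(5, 50)
            labels = np.where(rng.random(n) < 0.4, 1, -1)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_pair_count(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFolds:
    def test_folds_partition_samples(self):
        y = np.where(np.random.default_rng(1).random(53) < 0.3, 1, -1)
        folds = make_folds(y, 5, stratified=True, seed=4)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(53))
        for tr, te in folds:
            assert not set(tr) & set(te)

    def test_stratified_class_proportions_within_one_sample(self):
        y = np.array([1] * 23 + [-1] * 77)
        folds = make_folds(y, 10, stratified=True, seed=0)
        for _, te in folds:
            n_pos = (y[te] == 1).sum()
            expected = 23 * len(te) / 100
            assert abs(n_pos - expected) <= 1

    def test_unstratified_single_class_fold_raises(self):
        y = np.array([1] * 3 + [-1] * 27)
        with pytest.raises(ValueError, match="stratified"):
            # 10 folds of 3 on a 3-positive dataset must strand a class
            make_folds(y, 10, stratified=False, seed=1)


class TestWrapper:
    def test_singleton_grid_is_returned_unconditionally(self):
        ds = _fast_fixture()
        best, curve = wrapper_select_n(
            ds, CVConfig(outer_folds=3, inner_folds=3, n_grid=(20,), seed=0)
        )
        assert best == 20
        assert len(curve) == 1

    def test_grid_truncated_to_feature_count(self, caplog):
        ds = _fast_fixture()
        cfg = CVConfig(outer_folds=3, inner_folds=3, n_grid=(20, 30, 2000), seed=0)
        with caplog.at_level("WARNING"):
            best, curve = wrapper_select_n(ds, cfg)
        assert [n for n, _ in curve] == [20, 30]
        assert any("truncated" in r.message for r in caplog.records)

    def test_same_seed_reproduces_curve(self):
        ds = _fast_fixture()
        cfg = CVConfig(**FAST_CV, seed=5)
        b1, c1 = wrapper_select_n(ds, cfg)
        b2, c2 = wrapper_select_n(ds, cfg)
        assert b1 == b2 and c1 == c2


class TestNestedCV:
    def test_separable_data_scores_high(self):
        cfg = SyntheticConfig(
            n_samples=120, prevalence_positive=0.4,
            blocks=[BlockConfig("S", "continuous", 30, n_informative=10, effect_size=5.0)],
            seed=2,
        )
        ds, _ = generate_multiomics(cfg)
        rep = nested_cv_evaluate(ds, CVConfig(**FAST_CV, seed=2))
        assert rep.aggregate_auc >= 0.95

    def test_report_is_deterministic_under_fixed_seed(self):
        ds = _fast_fixture(seed=3)
        cfg = CVConfig(**FAST_CV, seed=3)
        r1 = nested_cv_evaluate(ds, cfg)
        r2 = nested_cv_evaluate(ds, cfg)
        assert r1.fold_aucs == r2.fold_aucs
        assert r1.chosen_n == r2.chosen_n
        assert r1.aggregate_auc == r2.aggregate_auc

    def test_chosen_n_always_in_grid(self):
        ds = _fast_fixture(seed=4)
        rep = nested_cv_evaluate(ds, CVConfig(**FAST_CV, seed=4))
        assert set(rep.chosen_n) <= {5, 10, 20}
        assert all(0 <= a <= 1 for a in rep.fold_aucs)

    def test_held_out_values_cannot_change_feature_selection(self):
        """Leakage canary: an absurd value planted in a held-out sample must
        not move the training-fold ranking or the wrapper choice."""
        ds = _fast_fixture(seed=5)
        folds = make_folds(ds.labels, 3, True, seed=5)
        tr, te = folds[0]
        cfg = CVConfig(**FAST_CV, seed=5)
        clean_train = ds.take(tr)
        best0, curve0 = wrapper_select_n(clean_train, cfg)
        ds.block("S").values[te[0], :] = 1e9  # poison one held-out row
        poisoned_train = ds.take(tr)
        best1, curve1 = wrapper_select_n(poisoned_train, cfg)
        assert best0 == best1 and curve0 == curve1


class TestExperimentSuite:
    @pytest.fixture(scope="class")
    @staticmethod
    def suite():
        ds = _fast_fixture(seed=6)
        return run_experiment_suite(ds, CVConfig(**FAST_CV, seed=6))

    def test_two_block_dataset_yields_five_reports(self, suite):
        assert [r.experiment for r in suite] == [
            "all-blocks", "single:S", "single:N", "drop:S", "drop:N",
        ]

    def test_fold_assignments_identical_across_experiments(self, suite):
        base = [f.test_indices.tolist() for f in suite[0].folds]
        for rep in suite[1:]:
            assert [f.test_indices.tolist() for f in rep.folds] == base

    def test_dropping_the_signal_block_hurts(self, suite):
        by_name = {r.experiment: r.aggregate_auc for r in suite}
        assert by_name["drop:S"] < by_name["all-blocks"]
        assert by_name["drop:S"] < by_name["drop:N"]


class TestFinalFeatureSet:
    def test_singleton_grid_gives_that_length(self):
        ds = _fast_fixture(seed=7)
        cfg = CVConfig(outer_folds=3, inner_folds=3, n_grid=(15,), seed=7)
        ranked, best_n, _ = final_feature_set(ds, cfg)
        assert best_n == 15 and len(ranked) == 15

    def test_deterministic_under_fixed_seed(self):
        ds = _fast_fixture(seed=8)
        cfg = CVConfig(**FAST_CV, seed=8)
        r1, n1, c1 = final_feature_set(ds, cfg)
        r2, n2, c2 = final_feature_set(ds, cfg)
        assert n1 == n2 and c1 == c2
        assert [e.ref for e in r1] == [e.ref for e in r2]


class TestCompositionSummary:
    def test_printed_count_table_reproduced(self):
        counts = {"CNV": 10, "Methylation": 21, "GeneExpression": 34,
                  "miRNA": 3, "Protein": 2}
        out = composition_summary(counts, list(counts))
        assert out["total"] == 70
        assert out["percentages"] == {
            "CNV": 14.29, "Methylation": 30.00, "GeneExpression": 48.57,
            "miRNA": 4.29, "Protein": 2.86,
        }

    def test_single_block_selection_is_all_of_it(self):
        out = composition_summary({"only": 12}, ["only"])
        assert out["percentages"] == {"only": 100.00}

    def test_annotated_subset_percentage(self):
        refs = [FeatureRef("b", f"f{i}", i) for i in range(18)]
        out = composition_summary({"b": 70}, ["b"], annotated=refs)
        assert out["annotated_count"] == 18
        assert out["annotated_percentage"] == 25.71

    def test_percentages_sum_to_hundred_after_rounding(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = {f"b{i}": int(c) for i, c in enumerate(rng.integers(1, 40, 5))}
            out = composition_summary(counts, list(counts))
            assert abs(sum(out["percentages"].values()) - 100.0) <= 0.02

    def test_counts_partition_a_ranked_list(self):
        ds = _fast_fixture(seed=10)
        from omicsmkl import OmicsMKL
        ranked = OmicsMKL(ds, cap=12).rank_features()
        out = composition_summary(ranked, ds.block_names)
        assert sum(out["counts"].values()) == len(ranked) == out["total"]
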