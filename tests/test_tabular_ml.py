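import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from venmorph.tabular_ml import (
    bootstrap_importance,
    classification_metrics,
    compare_groups,
    default_adapters,
    misclassified_by_at_least,
    rank_correlation_between_adapters,
    subsample_census,
)


def planted_table(n=120, m=12, seed=0):
    """Gaussian noise features with one feature fully determining the label.

    The signal feature carries a 0.5 margin around its threshold so tree
    learners separate the classes exactly (no borderline cells)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    X[:, 3] = np.sign(X[:, 3]) * (0.5 + np.abs(X[:, 3]))
    y = (X[:, 3] > 0).astype(int)
    df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(m)])
    df["label"] = np.where(y == 1, "VEN", "pyramidal")
    df.index = [f"cell_{i:03d}" for i in range(n)]
    df.index.name = "cell_id"
    return df


@pytest.fixture(scope="module")
def fast_adapters():
    keep = ("random_forest", "decision_tree")
    return [a for a in default_adapters(fast=True) if a.name in keep]


class TestBootstrapImportance:
    def test_planted_feature_dominates(self, fast_adapters):
        table = planted_table()
        ranking = bootstrap_importance(
            table, fast_adapters, subset_size=6, n_reps=60, seed=1
        )
        top = ranking.summary["first_position_frequency"].idxmax()
        assert top == "f03"
        assert ranking.summary.loc["f03", "median_rank"] == 1.0

    def test_single_full_subset_equals_model_order(self, fast_adapters):
        table = planted_table(n=80, m=6)
        ranking = bootstrap_importance(
            table, fast_adapters[:1], subset_size=6, n_reps=1, seed=2
        )
        included = ranking.summary["n_included"]
        assert (included == 1).all()
        # the single run covers every feature; ranks are a permutation of 1..6
        ad = ranking.per_adapter[fast_adapters[0].name]
        assert ad.loc["f03", "median_rank"] == 1.0

    def test_subset_size_validated(self, fast_adapters):
        with pytest.raises(ValueError, match="subset_size"):
            bootstrap_importance(
                planted_table(m=5), fast_adapters, subset_size=10, n_reps=1
            )

    def test_inclusion_counts_near_expectation(self, fast_adapters):
        table = planted_table(m=12)
        n_reps, k = 150, 6
        ranking = bootstrap_importance(
            table, fast_adapters[:1], subset_size=k, n_reps=n_reps, seed=3
        )
        expected = n_reps * k / 12
        sd = np.sqrt(n_reps * (k / 12) * (1 - k / 12))
        counts = ranking.summary["n_included"]
        assert ((counts >= expected - 3 * sd) & (counts <= expected + 3 * sd)).all()

    def test_reproducible_under_seed(self, fast_adapters):
        table = planted_table(n=60)
        a = bootstrap_importance(table, fast_adapters, subset_size=6, n_reps=10, seed=5)
        b = bootstrap_importance(table, fast_adapters, subset_size=6, n_reps=10, seed=5)
        pd.testing.assert_frame_equal(a.summary, b.summary)


class TestRankCorrelation:
    def _frame(self, ranks):
        return pd.DataFrame({"median_rank": ranks}, index=[f"f{i}" for i in range(len(ranks))])

    def test_identical_rankings(self):
        per = {"a": self._frame([1, 2, 3, 4]), "b": self._frame([1, 2, 3, 4])}
        mat, mean, sd = rank_correlation_between_adapters(per)
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)
        assert sd == 0.0

    def test_reversed_ranking(self):
        per = {"a": self._frame([1, 2, 3, 4]), "b": self._frame([4, 3, 2, 1])}
        _, mean, _ = rank_correlation_between_adapters(per)
        assert mean == pytest.approx(-1.0)

    def test_planted_signal_adapters_agree(self, fast_adapters):
        ranking = bootstrap_importance(
            planted_table(), fast_adapters, subset_size=6, n_reps=60, seed=7
        )
        _, mean, _ = rank_correlation_between_adapters(ranking.per_adapter)
        assert mean > 0.5

    def test_requires_two_adapters(self):
        with pytest.raises(ValueError):
            rank_correlation_between_adapters({"only": self._frame([1, 2, 3])})


class TestSubsampleCensus:
    def test_constant_predictor_misclassifies_all_positives(self):
        from venmorph.tabular_ml import ClassifierAdapter
        from sklearn.dummy import DummyClassifier

        table = planted_table(n=60)
        adapters = [
            ClassifierAdapter("always_zero", lambda s: DummyClassifier(
                strategy="constant", constant=0)),
            ClassifierAdapter("always_one", lambda s: DummyClassifier(
                strategy="constant", constant=1)),
        ]
        census = subsample_census(table, adapters, n_per_class=10, n_reps=5, seed=1)
        pos = census[
            (census["label"] == "VEN") & (census["always_zero__n_evaluations"] > 0)
        ]
        assert len(pos) > 0
        assert (pos["always_zero__fraction"] == 1.0).all()
        assert (pos["always_one__fraction"] == 0.0).all()

    def test_separable_cohort_clean_census(self, fast_adapters):
        table = planted_table(n=100)
        census = subsample_census(
            table, fast_adapters, n_per_class=30, n_reps=20, seed=2
        )
        assert misclassified_by_at_least(census, len(fast_adapters)) == []

    def test_label_flips_dominate_census(self, fast_adapters):
        table = planted_table(n=120)
        flipped = ["cell_005", "cell_028", "cell_054"]
        table = table.copy()
        table.loc[flipped, "label"] = np.where(
            table.loc[flipped, "label"] == "VEN", "pyramidal", "VEN"
        )
        census = subsample_census(
            table, fast_adapters, n_per_class=40, n_reps=30, seed=3
        )
        top3 = list(
            census.sort_values(
                "n_classifiers_misclassifying", ascending=False
            ).head(3).index
        )
        assert set(top3) == set(flipped)

    def test_class_size_validated(self, fast_adapters):
        with pytest.raises(ValueError, match="n_per_class"):
            subsample_census(planted_table(n=30), fast_adapters, n_per_class=50, n_reps=1)

    def test_census_reproducible(self, fast_adapters):
        table = planted_table(n=80)
        a = subsample_census(table, fast_adapters, n_per_class=20, n_reps=5, seed=9)
        b = subsample_census(table, fast_adapters, n_per_class=20, n_reps=5, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCompareGroups:
    def test_identical_groups_symmetric_null(self):
        vals = np.arange(8, dtype=float)
        df = pd.DataFrame({"x": np.concatenate([vals, vals])})
        mask = np.arange(16) < 8
        out = compare_groups(df, mask)
        assert out.loc["x", "U"] == pytest.approx(8 * 8 / 2)
        assert out.loc["x", "cohens_d"] == pytest.approx(0.0)

    def test_disjoint_groups_smaller_u_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        out = compare_groups(df, [True, True, False, False])
        assert out.loc["x", "U"] == 0.0

    def test_bonferroni_scaling(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.standard_normal((30, 20)), columns=[f"f{i}" for i in range(20)]
        )
        mask = np.arange(30) < 15
        out = compare_groups(df, mask)
        for f in out.index:
            assert out.loc[f, "p_adj"] == pytest.approx(
                min(1.0, 20 * out.loc[f, "p"])
            )

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 5)
        df = pd.DataFrame({"x": np.concatenate([a, b])})
        mask = np.arange(11) < 6
        out = compare_groups(df, mask)
        # brute force: count pairs won by each group over all 30 pairings
        u_a = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        )
        expected = min(u_a, len(a) * len(b) - u_a)
        assert out.loc["x", "U"] == pytest.approx(expected)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups(df, [True, True])


class TestClassificationMetrics:
    def test_printed_precision_recall_pair(self):
        # 48 true positives all recalled, 2 false positives → P .96, R 1.0
        y_true = np.array([1] * 48 + [0] * 52)
        y_pred = np.array([1] * 48 + [1, 1] + [0] * 50)
        m = classification_metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.96)
        assert m["recall"] == pytest.approx(1.0)
        assert round(m["f1"], 2) == 0.98

    def test_all_positive_predictor_on_balanced_truth(self):
        y_true = np.array([0, 1] * 20)
        y_pred = np.ones(40, dtype=int)
        m = classification_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(1.0)
        assert m["precision"] == pytest.approx(0.5)

    def test_perfect_ranking_auc(self):
        y_true = np.array([0, 0, 1, 1])
        m = classification_metrics(y_true, y_true, scores=[0.1, 0.2, 0.8, 0.9])
        assert m["roc_auc"] == pytest.approx(1.0)

    def test_single_class_truth_flags_auc(self):
        m = classification_metrics([1, 1], [1, 0], scores=[0.9, 0.1])
        assert m["roc_auc"] is None
        assert not m["auc_defined"]

    def test_f1_equals_precision_when_equal(self):
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 0, 1, 0])
        m = classification_metrics(y_true, y_pred)
        assert m["precision"] == m["recall"] == m["f1"]

    def test_auc_is_rank_statistic(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        m = classification_metrics(y, (s > 0.5).astype(int), scores=s)
        # brute-force pair counting
        pos, neg = s[y == 1], s[y == 0]
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p, n in itertools.product(pos, neg)
        )
        assert m["roc_auc"] == pytest.approx(wins / (len(pos) * len(neg)))


class TestNullImportance:
    def test_permuted_labels_no_dominant_feature(self, fast_adapters):
        rng = np.random.default_rng(11)
        table = planted_table(n=100, m=12, seed=11)
        table = table.copy()
        table["label"] = rng.permutation(table["label"].to_numpy())
        ranking = bootstrap_importance(
            table, fast_adapters, subset_size=6, n_reps=100, seed=12
        )
        assert ranking.summary["first_position_frequency"].max() <= 3 / 6
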