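"""Cross-validated pathway scoring, importance extraction and gene ranking."""

import numpy as np
import pandas as pd
import pytest

from mitocausal.containers import ValidationError
from mitocausal.pathway_ml import (
    CVConfig,
    ImportanceVector,
    ModelMetrics,
    PathwayScorecard,
    extract_importance,
    pathway_score,
    run_cv,
    score_pathways,
    select_best_model,
    select_top_pathways,
    total_importance,
)

from conftest import make_expression


def separable_matrix(rng, n=40, g=4, gap=10.0):
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    vals = rng.normal(0, 1, (n, g)) + gap * labels[:, None]
    return make_expression(vals, labels)


class TestRunCV:
    def test_separable_classes_perfect_accuracy(self, rng):
        em = separable_matrix(rng)
        cfg = CVConfig(n_folds=5, seed=0, model_set=["logistic_regression"])
        metrics = run_cv(em, cfg)
        assert metrics["logistic_regression"].means["accuracy"] == 1.0

    def test_permuted_labels_auc_near_half(self, rng):
        vals = rng.normal(0, 1, (200, 5))
        labels = rng.permutation([0] * 100 + [1] * 100)
        em = make_expression(vals, labels)
        cfg = CVConfig(n_folds=10, seed=1, model_set=["logistic_regression"])
        auc = run_cv(em, cfg)["logistic_regression"].means["roc_auc"]
        assert 0.4 <= auc <= 0.6

    def test_deterministic_under_seed(self, rng):
        em = separable_matrix(rng, gap=1.0)
        cfg = CVConfig(n_folds=5, seed=7, model_set=["random_forest"])
        a = run_cv(em, cfg)["random_forest"].fold_values
        b = run_cv(em, cfg)["random_forest"].fold_values
        pd.testing.assert_frame_equal(a, b)

    def test_fold_partition_is_stratified_partition(self, rng):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([0] * 30 + [1] * 20)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        seen = np.zeros(50, dtype=int)
        for _, va in skf.split(np.zeros((50, 1)), y):
            seen[va] += 1
            frac = y[va].mean()
            assert abs(frac * len(va) - 0.4 * len(va)) <= 1
        assert (seen == 1).all()

    def test_too_few_samples_per_class_rejected(self, rng):
        em = make_expression(rng.normal(0, 1, (6, 2)), [0, 0, 0, 0, 1, 1])
        with pytest.raises(ValidationError):
            run_cv(em, CVConfig(n_folds=5, model_set=["logistic_regression"]))


class TestSelectBestModel:
    @staticmethod
    def metrics_with_auc(auc):
        df = pd.DataFrame({"accuracy": [0.5], "roc_auc": [auc], "f1": [0.5],
                           "precision": [0.5], "recall": [0.5]})
        return ModelMetrics(df)

    def test_argmax_of_mean_auc(self):
        m = {"A": self.metrics_with_auc(0.7), "B": self.metrics_with_auc(0.9)}
        assert select_best_model(m) == "B"

    def test_tie_broken_by_listing_order(self):
        m = {"A": self.metrics_with_auc(0.8), "B": self.metrics_with_auc(0.8)}
        assert select_best_model(m) == "A"

    def test_single_model(self):
        assert select_best_model({"only": self.metrics_with_auc(0.6)}) == "only"


class _LinearStub:
    """Fitted linear model exposing only coef_ and predict."""

    def __init__(self, coef):
        self.coef_ = np.asarray([coef], dtype=float)

    def predict(self, X):
        return np.zeros(len(X))


class TestExtractImportance:
    def test_coefficients_normalized_by_max(self, rng):
        em = make_expression(rng.normal(0, 1, (4, 2)), [0, 0, 1, 1])
        iv = extract_importance(_LinearStub([2.0, -4.0]), em)
        assert iv.method == "coefficient-magnitude"
        np.testing.assert_allclose(iv.values.to_numpy(), [0.5, 1.0])

    def test_permutation_identifies_informative_gene(self, rng):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            labels = np.array([0] * 50 + [1] * 50)
            vals = np.column_stack([
                r.normal(0, 1, 100) + 3.0 * labels,  # informative
                r.normal(0, 1, 100),                 # pure noise
            ])
            em = make_expression(vals, labels)
            from sklearn.neighbors import KNeighborsClassifier
            knn = KNeighborsClassifier().fit(vals, labels)
            iv = extract_importance(knn, em, seed=s)
            hits += (iv.values.iloc[0] == 1.0 and iv.values.iloc[1] < 0.2)
        assert hits >= 9
        assert iv.method == "permutation"

    def test_constant_predictions_give_zero_vector(self, rng):
        class Constant:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X))

            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        em = make_expression(rng.normal(0, 1, (20, 3)), [0] * 10 + [1] * 10)
        iv = extract_importance(Constant(), em, seed=0, n_repeats=5)
        assert (iv.values == 0).all()

    def test_model_without_predict_rejected(self, rng):
        em = make_expression(rng.normal(0, 1, (4, 2)), [0, 0, 1, 1])
        with pytest.raises(ValidationError):
            extract_importance(object(), em)


class TestPathwayScore:
    def test_equal_metrics(self):
        means = dict(accuracy=0.8, roc_auc=0.8, f1=0.8, precision=0.8, recall=0.8)
        assert pathway_score(means) == pytest.approx(0.8, abs=1e-12)

    def test_one_zero_metric(self):
        means = dict(accuracy=1, roc_auc=1, f1=1, precision=1, recall=0)
        assert pathway_score(means) == pytest.approx(0.8, abs=1e-12)

    def test_missing_metric_rejected(self):
        with pytest.raises(ValidationError):
            pathway_score(dict(accuracy=0.9, roc_auc=0.9))

    def test_monotone_in_each_metric(self):
        base = dict(accuracy=0.6, roc_auc=0.7, f1=0.5, precision=0.6, recall=0.8)
        s0 = pathway_score(base)
        for key in base:
            bumped = dict(base)
            bumped[key] += 0.05
            assert pathway_score(bumped) > s0


def scorecard_from_scores(scores: dict) -> PathwayScorecard:
    table = pd.DataFrame({"score": pd.Series(scores),
                          "best_model": "m"})
    return PathwayScorecard(table, {p: {"m": None} for p in scores}, {})


class TestSelectTopPathways:
    def test_top_half_selected(self):
        sc = scorecard_from_scores({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.6})
        assert set(select_top_pathways(sc)) == {"a", "b"}

    def test_median_ties_included(self):
        sc = scorecard_from_scores({"a": 0.8, "b": 0.8, "c": 0.2})
        assert set(select_top_pathways(sc)) == {"a", "b"}

    def test_single_pathway_selected(self):
        sc = scorecard_from_scores({"solo": 0.5})
        assert select_top_pathways(sc) == ["solo"]


class TestTotalImportance:
    @staticmethod
    def card(importances: dict) -> PathwayScorecard:
        pathways = sorted({pw for pw, _ in importances})
        table = pd.DataFrame({"score": 1.0, "best_model": "m"},
                             index=pathways)
        metrics = {pw: {m: None for pw2, m in importances if pw2 == pw}
                   for pw in pathways}
        ivs = {key: ImportanceVector(pd.Series(vals), "coefficient-magnitude")
               for key, vals in importances.items()}
        return PathwayScorecard(table, metrics, ivs)

    def test_sum_across_pathways(self):
        sc = self.card({("p1", "m"): {"g": 0.5, "h": 1.0},
                        ("p2", "m"): {"g": 0.25, "k": 1.0}})
        ranking = total_importance(sc, ["p1", "p2"], {})
        assert ranking.table.loc["g", "total_importance"] == pytest.approx(0.75)

    def test_gene_outside_selected_pathways_absent(self):
        sc = self.card({("p1", "m"): {"g": 1.0}, ("p2", "m"): {"x": 1.0}})
        ranking = total_importance(sc, ["p1"], {})
        assert "x" not in ranking.table.index

    def test_ledger_additivity_and_order_invariance(self):
        imp = {("p1", "m"): {"g": 0.5, "h": 1.0},
               ("p2", "m"): {"g": 0.25, "h": 1.0}}
        a = total_importance(self.card(imp), ["p1", "p2"], {})
        b = total_importance(self.card(imp), ["p2", "p1"], {})
        recomputed = a.ledger.groupby("gene")["importance"].sum()
        pd.testing.assert_series_equal(
            a.table["total_importance"].sort_index(),
            recomputed.sort_index(), check_names=False)
        pd.testing.assert_frame_equal(a.table.sort_index(), b.table.sort_index())

    def test_normalization_bound(self):
        # with M models and P pathways, totals cannot exceed M*P
        imp = {(p, m): {"g": 1.0} for p in ("p1", "p2") for m in ("m", "m2")}
        sc = self.card(imp)
        ranking = total_importance(sc, ["p1", "p2"], {})
        assert ranking.table["total_importance"].max() <= 2 * 2 + 1e-12

    def test_unknown_mode_rejected(self):
        sc = self.card({("p1", "m"): {"g": 1.0}})
        with pytest.raises(ValidationError):
            total_importance(sc, ["p1"], {}, aggregation="median")


class TestScorePathways:
    def test_driver_gene_ranks_first(self, rng):
        # one gene carries the class signal in both pathways it belongs to
        labels = np.array([0] * 30 + [1] * 30)
        driver = rng.normal(0, 1, 60) + 4.0 * labels
        noise = rng.normal(0, 1, (60, 5))
        vals = np.column_stack([driver, noise])
        genes = ["DRIVER"] + [f"N{i}" for i in range(5)]
        em = make_expression(vals, labels, genes=genes)
        # two separable pathways carry the driver; two noise-only pathways
        # score lower and fall below the median, so both driver pathways
        # survive the top-half selection
        pmap = {"pw1": {"DRIVER", "N0", "N1"}, "pw2": {"DRIVER", "N2", "N3"},
                "pw3": {"N0", "N2", "N4"}, "pw4": {"N1", "N3", "N4"}}
        cfg = CVConfig(n_folds=5, seed=0, model_set=["logistic_regression"])
        sc = score_pathways(em, pmap, cfg)
        ranking = total_importance(sc, select_top_pathways(sc), pmap)
        assert ranking.table.index[0] == "DRIVER"
        assert ranking.table.loc["DRIVER", "n_contributions"] == 2
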