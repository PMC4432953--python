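import numpy as np
import pandas as pd
import pytest

from ishannot import (
    AnnotationTable,
    FeatureMatrix,
    annotate_level,
    auc,
    balanced_split,
    binarize,
    count_annotation_tasks,
    ontology_from_level_counts,
    score,
    train,
)
from ishannot.annotate import logistic_objective


def _table(rows):
    return AnnotationTable(pd.DataFrame(
        rows, columns=["gene_id", "structure_id", "metric", "category"]))


def _maps(labels_by_structure):
    return {sid: pd.Series(list(vals.values()), index=list(vals))
            for sid, vals in labels_by_structure.items()}


class TestBinarize:
    def test_undetected_maps_to_negative_everything_else_positive(self):
        table = _table([("g1", "s1", "pattern", "undetected"),
                        ("g2", "s1", "pattern", "full"),
                        ("g3", "s1", "pattern", "gradient")])
        maps = binarize(table, "pattern")
        assert maps["s1"].to_dict() == {"g1": -1, "g2": 1, "g3": 1}

    def test_all_undetected_structure_is_single_class(self):
        table = _table([("g1", "s1", "pattern", "undetected"),
                        ("g2", "s1", "pattern", "undetected")])
        assert set(binarize(table)["s1"]) == {-1}

    def test_three_metrics_induce_identical_tasks_on_consistent_tables(self):
        rows = []
        for g, cat in [("g1", "full"), ("g2", "undetected"), ("g3", "regional")]:
            rows.append((g, "s1", "pattern", cat))
            lvl = "undetected" if cat == "undetected" else "median"
            rows.append((g, "s1", "intensity", lvl))
            rows.append((g, "s1", "density", lvl))
        table = _table(rows)
        maps = [binarize(table, m)["s1"] for m in ("pattern", "intensity", "density")]
        assert maps[0].equals(maps[1]) and maps[1].equals(maps[2])

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            binarize(_table([("g1", "s1", "pattern", "full")]), "shape")

    def test_genes_without_records_are_absent_from_the_map(self):
        table = _table([("g1", "s1", "pattern", "full"),
                        ("g2", "s2", "pattern", "undetected")])
        assert "g2" not in binarize(table)["s1"].index


class TestBalancedSplit:
    def test_balanced_data_accepted_at_the_initial_threshold(self):
        labels = {f"g{i}": (1 if i % 2 else -1) for i in range(12)}
        res = balanced_split(_maps({"s1": labels}), threshold_start=0.5, seed=2)
        assert res.n_attempts == 1  # this seed's first draw is balanced enough
        assert res.achieved_threshold == 0.5
        assert len(res.train_genes) == 8 and len(res.test_genes) == 4

    def test_single_class_structure_excluded_and_flagged(self):
        maps = _maps({
            "ok": {f"g{i}": (1 if i % 2 else -1) for i in range(12)},
            "degenerate": {f"g{i}": -1 for i in range(12)},
        })
        res = balanced_split(maps, threshold_start=0.3, seed=1)
        assert res.excluded_structures == ["degenerate"]
        assert len(res.train_genes) + len(res.test_genes) == 12

    def test_threshold_relaxes_after_exhausting_max_attempts(self):
        # 6 genes, 2 positives, halves of 3: the best any split can do is
        # 1 pos + 2 neg in each half, a minority ratio of 1/2, so a 0.9
        # starting threshold is unsatisfiable and the schedule must engage.
        # Oracle: after k exhausted rounds the threshold is start * decay**k;
        # acceptance first becomes possible once 0.9 * 0.8**k <= 1/2.
        labels = {"g0": 1, "g1": 1, "g2": -1, "g3": -1, "g4": -1, "g5": -1}
        res = balanced_split(
            _maps({"s1": labels}), train_fraction=0.5, max_attempts=10,
            threshold_start=0.9, threshold_decay=0.8, seed=3,
        )
        assert res.achieved_threshold < 0.9
        assert res.n_attempts > 10
        k = int(np.ceil(np.log(0.5 / 0.9) / np.log(0.8)))
        assert res.achieved_threshold == pytest.approx(0.9 * 0.8 ** k)

    def test_deterministic_under_seed(self):
        labels = {f"g{i}": (1 if i % 3 else -1) for i in range(15)}
        a = balanced_split(_maps({"s1": labels}), seed=5)
        b = balanced_split(_maps({"s1": labels}), seed=5)
        assert a.train_genes == b.train_genes and a.test_genes == b.test_genes

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            balanced_split(_maps({"s1": {"g0": 1}}))


class TestTrain:
    def _toy(self, n=40, seed=0):
        g = np.random.default_rng(seed)
        X = g.standard_normal((n, 2))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1, -1)
        X[y == 1] += 2.0  # make it separable
        return X, y.astype(float)

    def test_huge_lambda_shrinks_weights_and_bias_matches_class_ratio_sign(self):
        g = np.random.default_rng(1)
        X = g.standard_normal((30, 3))
        y = np.concatenate([np.ones(20), -np.ones(10)])
        model = train(X, y, lam=1e8)
        assert np.linalg.norm(model.w) < 1e-3
        assert np.sign(model.b) == np.sign(np.log(20 / 10))

    def test_separable_data_reaches_perfect_training_accuracy(self):
        X, y = self._toy()
        model = train(X, y, lam=1e-4)
        assert np.all(np.sign(score(model, X)) == y)

    def test_analytic_gradient_matches_central_differences(self):
        g = np.random.default_rng(2)
        X = g.standard_normal((15, 4))
        y = np.where(g.random(15) > 0.5, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        eps = 1e-6
        for _ in range(10):
            theta = g.standard_normal(5)
            _, grad = logistic_objective(theta, X, y, lam=0.7)
            num = np.empty_like(theta)
            for j in range(5):
                e = np.zeros(5)
                e[j] = eps
                fp, _ = logistic_objective(theta + e, X, y, 0.7)
                fm, _ = logistic_objective(theta - e, X, y, 0.7)
                num[j] = (fp - fm) / (2 * eps)
            np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-7)

    def test_objective_trace_is_monotone_nonincreasing(self):
        X, y = self._toy(seed=4)
        model = train(X, y, lam=0.5)
        trace = np.asarray(model.trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-8 * np.abs(trace[:-1]) + 1e-10)

    def test_single_class_and_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((4, 2)), np.ones(4))
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train(X, np.array([1, -1, 1, -1.0]))


class TestScore:
    def test_zero_model_scores_zero(self):
        from ishannot.annotate import LinearModel
        model = LinearModel(np.zeros(3), 0.0, 1.0)
        np.testing.assert_array_equal(score(model, np.ones((5, 3))), 0.0)

    def test_doubling_parameters_doubles_scores(self):
        from ishannot.annotate import LinearModel
        g = np.random.default_rng(3)
        X = g.standard_normal((6, 4))
        m1 = LinearModel(g.standard_normal(4), 0.3, 1.0)
        m2 = LinearModel(2 * m1.w, 2 * m1.b, 1.0)
        np.testing.assert_allclose(score(m2, X), 2 * score(m1, X))

    def test_matches_per_row_dot_product_loop(self):
        from ishannot.annotate import LinearModel
        g = np.random.default_rng(4)
        X = g.standard_normal((7, 3))
        model = LinearModel(g.standard_normal(3), -0.2, 1.0)
        s = score(model, X)
        for i in range(7):
            expected = sum(model.w[j] * X[i, j] for j in range(3)) + model.b
            assert s[i] == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        from ishannot.annotate import LinearModel
        with pytest.raises(ValueError):
            score(LinearModel(np.ones(3), 0.0, 1.0), np.ones((2, 4)))


def _pairwise_auc(scores, labels):
    """O(n+ n-) comparison oracle: wins + half ties."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ordering(self):
        assert auc(np.array([3.0, 2.0, 1.0]), np.array([1, 1, -1])) == 1.0

    def test_pure_ties_give_half(self):
        assert auc(np.zeros(6), np.array([1, 1, 1, -1, -1, -1])) == 0.5

    def test_matches_pairwise_oracle_on_random_sets(self):
        g = np.random.default_rng(6)
        for _ in range(50):
            n = int(g.integers(4, 30))
            labels = np.where(g.random(n) > 0.5, 1, -1)
            if len(np.unique(labels)) < 2:
                labels[0] = -labels[0]
            scores = np.round(g.standard_normal(n), 1)  # induce ties
            assert auc(scores, labels) == pytest.approx(
                _pairwise_auc(scores, labels))

    def test_invariant_under_strictly_monotone_transforms(self):
        g = np.random.default_rng(7)
        scores = g.standard_normal(40)
        labels = np.where(g.random(40) > 0.6, 1, -1)
        labels[:2] = [1, -1]
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base)
        assert auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(3), np.ones(3))


class TestAnnotateLevel:
    def test_one_task_per_structure_for_the_atlas_level_counts(self):
        counts = [3, 6, 19, 14, 81, 46, 123, 40, 307, 432]
        ont = ontology_from_level_counts(counts)
        assert count_annotation_tasks(ont) == 1071

    def test_gene_order_permutation_leaves_the_report_unchanged(self):
        g = np.random.default_rng(8)
        ont = ontology_from_level_counts([2])
        genes = [f"g{i}" for i in range(24)]
        rows = []
        for gi, gene in enumerate(genes):
            for sid in ont.ids():
                cat = "full" if (gi + hash(sid)) % 2 else "undetected"
                rows.append((gene, sid, "pattern", cat))
        table = _table(rows)
        X = g.standard_normal((24, 6))
        fm = FeatureMatrix(X, genes, "bow")
        perm = g.permutation(24)
        fm_perm = FeatureMatrix(X[perm], [genes[i] for i in perm], "bow")
        table_perm = AnnotationTable(
            table.frame.sample(frac=1.0, random_state=1).reset_index(drop=True))
        a = annotate_level(fm, table, ont, level=1, seed=2)
        b = annotate_level(fm_perm, table_perm, ont, level=1, seed=2)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_level_without_eligible_structures_gives_empty_report(self):
        ont = ontology_from_level_counts([1])
        table = _table([("g0", "L1_000", "pattern", "undetected"),
                        ("g1", "L1_000", "pattern", "undetected")])
        fm = FeatureMatrix(np.zeros((2, 3)), ["g0", "g1"], "bow")
        report = annotate_level(fm, table, ont, level=1, seed=0)
        assert len(report.rows) == 0
        assert np.isnan(report.overall_auc)
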