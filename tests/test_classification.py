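"""Scores, metrics, pair enumeration/selection, RFE, final evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stratify.classification import (
    EvalProtocol,
    SelectionError,
    a_score,
    confusion_from_rates,
    enumerate_eligible_pairs,
    evaluate_pair,
    final_evaluation,
    metrics_from_confusion,
    rfe_select,
    s_score,
    select_congenic_pair,
)
from stratify.datatypes import InvalidArgumentError

from conftest import gaussian_feature_table

PAPER_COHORT = pd.DataFrame(
    {
        "group": ["Dll4+", "Dll4-", "CG1", "CG2", "CG3", "CG4", "CG5", "CG6", "CG7", "CG8"],
        "dll4_label": ["high", "low", "high", "low", "low", "low", "high", "high", "low", "low"],
        "n": [8, 17, 19, 2, 26, 12, 28, 12, 5, 4],
    }
)


class TestAScore:
    @pytest.mark.parametrize(
        "acc,sens,spec,expected",
        [(1, 1, 1, 1.0), (0, 0, 0, 0.0), (1, 0.6, 1, 0.8666666666666667)],
    )
    def test_arithmetic_mean(self, acc, sens, spec, expected):
        assert a_score(acc, sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            a_score(1.2, 0.5, 0.5)


class TestSScore:
    @pytest.mark.parametrize(
        "a1,a2,a3,expected",
        [(1, 1, 1, 1.0), (0, 0, 0, 0.0), (0.92, 0.83, 0.8, 0.8375)],
    )
    def test_weighted_mean(self, a1, a2, a3, expected):
        assert s_score(a1, a2, a3) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 0.2), st.integers(0, 2),
    )
    def test_bounded_and_monotone(self, a1, a2, a3, delta, which):
        base = s_score(a1, a2, a3)
        assert 0 <= base <= 1
        args = [a1, a2, a3]
        args[which] = min(args[which] + delta, 1.0)
        assert s_score(*args) >= base - 1e-12


class TestMetricsFromConfusion:
    def test_perfect_classifier(self):
        p = metrics_from_confusion(5, 0, 0, 7)
        for metric in ("sensitivity", "specificity", "precision", "accuracy", "f1", "mcc"):
            assert getattr(p, metric) == 1.0

    def test_zero_marginal_gives_zero_mcc(self):
        p = metrics_from_confusion(0, 0, 3, 7)  # no positives in truth or prediction?
        assert p.mcc == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidArgumentError):
            metrics_from_confusion(0, 0, 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_metric_identities(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        p = metrics_from_confusion(tp, fn, fp, tn)
        if tp + fn:
            assert p.sensitivity == pytest.approx(tp / (tp + fn))
            assert p.fnr == pytest.approx(1 - p.sensitivity)
        if tn + fp:
            assert p.specificity == pytest.approx(tn / (tn + fp))
            assert p.fpr == pytest.approx(1 - p.specificity)
        assert p.accuracy == pytest.approx((tp + tn) / (tp + fn + fp + tn))
        if p.precision + p.sensitivity > 0:
            assert p.f1 == pytest.approx(
                2 * p.precision * p.sensitivity / (p.precision + p.sensitivity)
            )
        assert -1 <= p.mcc <= 1


class TestConfusionFromRates:
    def test_minimal_perfect_matrix(self):
        assert confusion_from_rates(1, 1, 1, 1, 1) == (1, 0, 0, 1)

    def test_mcc_f1_invariant_under_scaling(self):
        base = metrics_from_confusion(6, 0, 2, 9)
        scaled = metrics_from_confusion(18, 0, 6, 27)
        assert base.mcc == pytest.approx(scaled.mcc)
        assert base.f1 == pytest.approx(scaled.f1)

    def test_inconsistent_rates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            confusion_from_rates(0.3333, 0.9999, 0.1234, 0.9876, 0.0001, max_total=60)


class TestEnumerateEligiblePairs:
    def test_published_cohort_yields_12_pairs(self):
        pairs = enumerate_eligible_pairs(PAPER_COHORT)
        assert len(pairs) == 12
        assert set(pairs) == {
            (h, l)
            for h in ("CG1", "CG5", "CG6", "Dll4+")
            for l in ("CG3", "CG4", "Dll4-")
        }

    def test_all_small_groups_give_empty_list(self):
        table = PAPER_COHORT.assign(n=5)
        assert enumerate_eligible_pairs(table) == []

    def test_single_pair(self):
        table = pd.DataFrame(
            {"group": ["A", "B"], "dll4_label": ["high", "low"], "n": [10, 6]}
        )
        assert enumerate_eligible_pairs(table) == [("A", "B")]

    def test_per_animal_table_counted(self, default_feature_table):
        pairs = enumerate_eligible_pairs(default_feature_table[["group", "dll4_label"]])
        assert len(pairs) == 12


class TestEvaluatePair:
    def test_perfectly_separated_classes_reach_a_score_one(self):
        table = gaussian_feature_table(n_per_group=16, gap=30.0, seed=0)
        ev = evaluate_pair(
            table, "A", "B", models=("linear_svm",),
            protocol=EvalProtocol(n_repeats=5, inner_cv_folds=3, base_seed=0),
        )
        assert ev.a_score_best == pytest.approx(1.0)
        assert ev.a_score_mean == pytest.approx(1.0)

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(3)
        table = gaussian_feature_table(n_per_group=20, gap=3.0, seed=3)
        table["group"] = rng.permutation(table["group"].to_numpy())
        table["dll4_label"] = np.where(table["group"] == "A", "high", "low")
        ev = evaluate_pair(
            table, "A", "B", models=("linear_svm",),
            protocol=EvalProtocol(n_repeats=20, inner_cv_folds=3, base_seed=0),
        )
        accs = [p.accuracy for p in ev.panels["linear_svm"]]
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_reproducible_from_base_seed(self):
        table = gaussian_feature_table(n_per_group=12, gap=2.0, seed=1)
        protocol = EvalProtocol(n_repeats=4, inner_cv_folds=3, base_seed=9)
        a = evaluate_pair(table, "A", "B", models=("decision_tree",), protocol=protocol)
        b = evaluate_pair(table, "A", "B", models=("decision_tree",), protocol=protocol)
        assert a.a_score_mean == b.a_score_mean
        assert [p.as_dict() for p in a.panels["decision_tree"]] == [
            p.as_dict() for p in b.panels["decision_tree"]
        ]

    def test_tiny_group_rejected(self):
        table = gaussian_feature_table(n_per_group=1, gap=2.0)
        with pytest.raises(InvalidArgumentError):
            evaluate_pair(table, "A", "B")


class TestRfeSelect:
    def test_planted_features_recovered(self):
        """Two informative columns among ten noise columns are found."""
        hits = 0
        for seed in range(20):
            table = gaussian_feature_table(
                n_per_group=25, n_features=12, informative=(2, 7),
                gap=2.5, seed=seed,
            )
            names, _ = rfe_select(
                table, ("A", "B"), "linear_svm", 2,
                EvalProtocol(base_seed=seed, inner_cv_folds=3),
            )
            hits += set(names) == {"f2", "f7"}
        assert hits >= 18

    def test_no_elimination_when_n_final_equals_total(self):
        table = gaussian_feature_table(n_per_group=10, n_features=4)
        names, _ = rfe_select(table, ("A", "B"), "linear_svm", 4)
        assert names == ["f0", "f1", "f2", "f3"]

    def test_constant_columns_dropped_first(self):
        table = gaussian_feature_table(n_per_group=15, n_features=5, gap=3.0)
        table["f4"] = 1.0  # constant
        names, _ = rfe_select(table, ("A", "B"), "linear_svm", 3)
        assert "f4" not in names


class TestSelectCongenicPair:
    @staticmethod
    def _multi_group_table(strong_gap=4.0, weak_gap=1.0, seed=0):
        groups = [
            ("P+", "high", strong_gap), ("P-", "low", 0.0),
            ("H1", "high", strong_gap), ("L1", "low", 0.0),
            ("H2", "high", weak_gap + 0.01), ("L2", "low", 0.01),
        ]
        rng = np.random.default_rng(seed)
        rows = []
        for name, label, shift in groups:
            for i in range(12):
                feats = rng.normal(0, 1, 4)
                feats[0] += shift
                feats[1] += shift / 2
                row = {"animal_id": f"{name}{i}", "group": name, "dll4_label": label}
                row.update({f"f{j}": feats[j] for j in range(4)})
                rows.append(row)
        return pd.DataFrame(rows)

    def test_dominant_pair_selected(self):
        table = self._multi_group_table()
        sel = select_congenic_pair(
            table,
            protocol=EvalProtocol(n_repeats=3, inner_cv_folds=3, base_seed=0),
            parental_high="P+",
            parental_low="P-",
        )
        assert sel.selected_pair == ("H1", "L1")
        assert len(sel.stage1) == 4  # H1/H2 x L1/L2

    def test_no_separation_fails_selection(self):
        table = self._multi_group_table(strong_gap=0.0, weak_gap=0.0)
        with pytest.raises(SelectionError):
            select_congenic_pair(
                table,
                protocol=EvalProtocol(n_repeats=3, inner_cv_folds=3, base_seed=0),
                parental_high="P+",
                parental_low="P-",
            )

    def test_identical_pairs_tie_break_is_lexicographic(self):
        base = self._multi_group_table()
        # duplicate the dominant pair's animals under new group names so two
        # congenic pairs are identical by construction
        dup = base[base["group"].isin(["H1", "L1"])].copy()
        dup["group"] = dup["group"].map({"H1": "H0", "L1": "L0"})
        dup["animal_id"] = dup["animal_id"] + "_dup"
        table = pd.concat([base, dup], ignore_index=True)
        sel = select_congenic_pair(
            table,
            protocol=EvalProtocol(n_repeats=3, inner_cv_folds=3, base_seed=0),
            parental_high="P+",
            parental_low="P-",
        )
        assert sel.selected_pair == ("H0", "L0")  # lexicographically first


class TestFinalEvaluation:
    def test_separable_classes_give_high_auc(self):
        table = gaussian_feature_table(
            n_per_group=25, n_features=4, informative=(0, 1), gap=4.0, seed=0,
            groups=(("A", "high"), ("B", "low"), ("C", "high"), ("D", "low")),
        )
        res = final_evaluation(
            table, ["A", "B", "C", "D"], ["f0", "f1"],
            models=("linear_svm",),
            protocol=EvalProtocol(n_repeats=1, inner_cv_folds=3, base_seed=0),
        )
        assert res["linear_svm"].auc >= 0.95

    def test_constant_scores_give_auc_half(self):
        table = gaussian_feature_table(n_per_group=20, n_features=3, gap=2.0)
        table["f2"] = 1.0  # constant feature -> constant decision scores
        res = final_evaluation(
            table, ["A", "B"], ["f2"], models=("linear_svm",),
            protocol=EvalProtocol(n_repeats=1, inner_cv_folds=3, base_seed=0),
        )
        assert res["linear_svm"].auc == 0.5

    def test_single_class_training_rejected(self):
        table = gaussian_feature_table(n_per_group=10)
        with pytest.raises(InvalidArgumentError):
            final_evaluation(table, ["A"], ["f0"])

    def test_missing_feature_rejected(self):
        table = gaussian_feature_table(n_per_group=10)
        with pytest.raises(InvalidArgumentError):
            final_evaluation(table, ["A", "B"], ["not_a_feature"])

    def test_report_files_written(self, tmp_path):
        table = gaussian_feature_table(n_per_group=15, gap=3.0)
        report = tmp_path / "report.json"
        roc = tmp_path / "roc.csv"
        final_evaluation(
            table, ["A", "B"], ["f0"], models=("linear_svm", "knn"),
            protocol=EvalProtocol(n_repeats=1, inner_cv_folds=3, base_seed=0),
            report_path=report, roc_path=roc,
        )
        import json

        payload = json.loads(report.read_text())
        assert set(payload) == {"linear_svm", "knn"}
        assert "test" in payload["linear_svm"]
        assert pd.read_csv(roc).shape[0] >= 4
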