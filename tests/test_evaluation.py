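"""Metrics, folds, ROC/AUC, cross-validation bookkeeping, suggestions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdscreen.base_classifiers import ContractError
from rdscreen.data_model import encode_records
from rdscreen.evaluation import (
    ConfusionMatrix,
    MetricError,
    StratificationError,
    aggregate_sensitivity,
    cross_validate,
    evaluate_questionnaire,
    roc_auc,
    sensitivity,
    specificity,
    stratified_folds,
    suggest_from_probabilities,
    truncate_percent,
)
from rdscreen.fusion import train_fusion
from rdscreen.subset_design import SubsetDataset
from rdscreen.synthetic_cohort import (
    EffectSpec,
    generate_cohort,
    shift_profile,
    uniform_profile,
)

from conftest import brute_force_auc


class TestMetricArithmetic:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(TP=79, FN=11, FP=12, TN=78), 87.7),
            (ConfusionMatrix(TP=84, FN=6, FP=11, TN=79), 93.3),
            (ConfusionMatrix(TP=36, FN=6, FP=6, TN=32), 85.7),
            (ConfusionMatrix(TP=10, FN=0, FP=0, TN=0), 100.0),
        ],
    )
    def test_sensitivity_truncated_to_one_decimal(self, cm, expected):
        assert sensitivity(cm) == expected

    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(TP=79, FN=11, FP=12, TN=78), 86.6),
            (ConfusionMatrix(TP=84, FN=6, FP=11, TN=79), 87.7),
            (ConfusionMatrix(TP=36, FN=6, FP=6, TN=32), 84.2),
            (ConfusionMatrix(TP=0, FN=0, FP=5, TN=0), 0.0),
        ],
    )
    def test_specificity_truncated_to_one_decimal(self, cm, expected):
        assert specificity(cm) == expected

    def test_truncation_cuts_rather_than_rounds(self):
        assert truncate_percent(87.78) == 87.7
        assert truncate_percent(86.66) == 86.6
        assert truncate_percent(100.0) == 100.0

    def test_undefined_metrics_raise(self):
        with pytest.raises(MetricError):
            sensitivity(ConfusionMatrix(TP=0, FN=0, FP=3, TN=3))
        with pytest.raises(MetricError):
            specificity(ConfusionMatrix(TP=3, FN=3, FP=0, TN=0))

    def test_headline_aggregation_is_the_mean(self):
        assert aggregate_sensitivity([87.7, 93.3, 85.7]) == 88.9
        assert aggregate_sensitivity([0.0, 0.0, 0.0]) == 0.0

    @given(x=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_aggregation_is_idempotent_on_equal_values(self, x):
        v = x / 10.0  # one-decimal percentages
        assert aggregate_sensitivity([v, v, v]) == v

    def test_aggregation_requires_three_values(self):
        with pytest.raises(ContractError):
            aggregate_sensitivity([90.0, 80.0])


class TestStratifiedFolds:
    def test_balanced_90_90_folds_are_9_plus_9(self):
        labels = [0] * 90 + [1] * 90
        folds = stratified_folds(labels, k=10, seed=0)
        labels = np.array(labels)
        for held in folds:
            assert np.sum(labels[held] == 0) == 9
            assert np.sum(labels[held] == 1) == 9

    def test_42_38_folds_split_class2_in_3s_and_4s(self):
        labels = np.array([0] * 42 + [1] * 38)
        folds = stratified_folds(labels, k=10, seed=0)
        for held in folds:
            assert np.sum(labels[held] == 1) in (3, 4)

    def test_folds_partition_all_indices(self):
        labels = [0] * 42 + [1] * 38
        folds = stratified_folds(labels, k=10, seed=1)
        flat = np.concatenate(folds)
        assert sorted(flat.tolist()) == list(range(80))

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(StratificationError):
            stratified_folds([0] * 50 + [1] * 5, k=10, seed=0)


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        scores = [(0, 0.9), (0, 0.8), (1, 0.2), (1, 0.1)]
        _, auc = roc_auc(scores)
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([(0, 0.5), (0, 0.6)])

    def test_matches_pair_counting_oracle_exhaustively_at_small_size(self):
        # all label patterns and tied score grids up to 5 samples
        levels = (0.0, 0.5, 1.0)
        for n in range(2, 6):
            for labels in itertools.product((0, 1), repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.product(levels, repeat=n):
                    pairs = list(zip(labels, scores))
                    _, auc = roc_auc(pairs)
                    assert auc == pytest.approx(brute_force_auc(pairs), abs=1e-12)

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 10)), min_size=2, max_size=12
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_pair_counting_oracle_on_random_tied_lists(self, data):
        labels = [lab for lab, _ in data]
        if len(set(labels)) < 2:
            return
        pairs = [(lab, s / 10.0) for lab, s in data]
        _, auc = roc_auc(pairs)
        assert auc == pytest.approx(brute_force_auc(pairs), abs=1e-12)


@pytest.fixture(scope="module")
def small_dataset(small_cohort):
    return SubsetDataset(
        subset_id=1,
        records=list(small_cohort.records),
        labels=np.array([0] * 30 + [1] * 30),
        class1_label="RD1",
        class2_label="NRO",
    )


@pytest.fixture(scope="module")
def report(small_dataset):
    return cross_validate(small_dataset, k=5, k_inner=3, seed=0)


class TestCrossValidation:
    def test_confusion_totals_conserve_sample_count(self, report, small_dataset):
        for clf, cm in report.confusions.items():
            assert cm.total == len(small_dataset.records), clf

    def test_stored_metrics_recomputable_from_matrices(self, report):
        for clf, cm in report.confusions.items():
            assert report.sensitivities[clf] == sensitivity(cm)
            assert report.specificities[clf] == specificity(cm)

    def test_separable_cohort_fusion_is_perfect(self, report):
        assert report.sensitivities["FUSION"] == 100.0
        assert report.specificities["FUSION"] == 100.0
        assert report.auc == 1.0

    def test_fold_provenance_covers_every_record_once(self, report, small_dataset):
        flat = [rid for fold in report.fold_record_ids for rid in fold]
        assert sorted(flat) == sorted(small_dataset.record_ids)

    def test_report_serializes_to_json(self, report):
        text = report.to_json()
        assert '"subset_id": 1' in text and '"FUSION"' in text


class TestSuggestionRule:
    @pytest.mark.parametrize(
        "triple,expected_suggestion,expected_p",
        [
            ((0.40, 0.76, 0.79), "RD (subset 3)", 0.79),
            ((0.06, 0.20, 0.30), "NRO", 0.94),
            ((0.30, 0.08, 0.30), "CD", 0.92),
            ((0.30, 0.30, 0.22), "PSY", 0.78),
            ((0.50, 0.50, 0.50), "RD (subset 1)", 0.50),  # ties alarm to RD
        ],
    )
    def test_documented_rule(self, triple, expected_suggestion, expected_p):
        result = suggest_from_probabilities(triple)
        assert result.suggestion == expected_suggestion
        assert result.headline_probability == pytest.approx(expected_p)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ContractError):
            suggest_from_probabilities((1.2, 0.5, 0.5))
        with pytest.raises(ContractError):
            suggest_from_probabilities((0.5, 0.5))


@pytest.fixture(scope="module")
def three_models():
    base = uniform_profile("base")
    models = {}
    for sid, alt in ((1, "NRO"), (2, "CD"), (3, "PSY")):
        profiles = {
            "RD": shift_profile(base, EffectSpec(delta=0.8), label="RD"),
            alt: uniform_profile(alt),
        }
        book = generate_cohort(profiles, 20, seed=sid)
        X = encode_records(book.records)
        y = np.array([0] * 20 + [1] * 20)
        bundle, fus, _ = train_fusion(X, y, k_inner=4, seed=sid, subset_id=sid)
        models[sid] = (bundle, fus)
    return models


class TestQuestionnaireEvaluation:
    def test_rare_disease_pattern_yields_rd_suggestion(self, three_models):
        base = uniform_profile("base")
        book = generate_cohort(
            {"RD": shift_profile(base, EffectSpec(delta=0.8), label="RD")}, 1, seed=99
        )
        triple = evaluate_questionnaire(book.records[0], three_models)
        assert triple.suggestion.startswith("RD")
        assert all(0.0 <= p <= 1.0 for p in triple.probabilities)

    def test_missing_model_is_contract_error(self, three_models):
        base = uniform_profile("base")
        book = generate_cohort({"NRO": base}, 1, seed=5)
        partial = {1: three_models[1], 2: three_models[2]}
        with pytest.raises(ContractError, match="subset 3"):
            evaluate_questionnaire(book.records[0], partial)
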