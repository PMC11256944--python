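import numpy as np
import pandas as pd
import pytest

from qmsdr import (
    ConfigError,
    EvaluationError,
    IntegrityError,
    ValidationError,
    concordance,
    ensemble_predict,
    f1_eval,
    fisher_r_to_z_test,
    label_response_classes,
    make_split_plan,
    marker_point,
    pearson_eval,
    pr_curve,
    recall_at_precision,
    run_nested_cv,
    survival_stratify,
)
from qmsdr.evaluate import ClinicalCohort, _check_partitions
from qmsdr.features import EncodingConfig, FeatureMatrix
from qmsdr.io import GenePanel


class TestSplitPlan:
    def test_fraction_sizes(self):
        plan = make_split_plan([f"s{i}" for i in range(1000)], seed=0)
        for repeat in plan.repeats:
            assert (len(repeat["train"]), len(repeat["val"]), len(repeat["test"])) == (
                700, 150, 150,
            )

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(97)]
        plan = make_split_plan(ids, seed=1)
        for repeat in plan.repeats:
            union = set(repeat["train"]) | set(repeat["val"]) | set(repeat["test"])
            assert union == set(ids)
            assert len(repeat["train"]) + len(repeat["val"]) + len(repeat["test"]) == 97

    def test_same_seed_reproduces_plan(self):
        ids = [f"s{i}" for i in range(50)]
        assert make_split_plan(ids, seed=5).repeats == make_split_plan(ids, seed=5).repeats

    def test_pooled_test_union_matches_inclusion_exclusion(self):
        n = 1244
        plan = make_split_plan([f"s{i}" for i in range(n)], n_repeats=5, seed=0)
        union = set()
        for repeat in plan.repeats:
            union |= set(repeat["test"])
        expected = n * (1 - 0.85**5)  # ~695
        assert abs(len(union) - expected) < 40

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            make_split_plan([f"s{i}" for i in range(50)], fractions=(0.5, 0.2, 0.2))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            make_split_plan(["a", "b", "c"])

    def test_overlapping_partition_detected(self):
        with pytest.raises(IntegrityError):
            _check_partitions({"train": ("a", "b"), "val": ("b",), "test": ("c",)})


class TestPearson:
    def test_perfect_correlations(self):
        y = np.array([0.1, 0.4, 0.8, 0.9])
        assert pearson_eval(y, y) == pytest.approx(1.0)
        assert pearson_eval(-y, y) == pytest.approx(-1.0)

    def test_four_point_worked_example(self):
        assert pearson_eval([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(EvaluationError):
            pearson_eval([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestFisherRtoZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_r_to_z_test(0.4, 100, 0.4, 80)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_worked_example(self):
        z, p = fisher_r_to_z_test(0.5, 103, 0.0, 103)
        assert z == pytest.approx(3.884, abs=1e-3)
        assert p < 0.001

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z_test(0.6, 50, 0.2, 70)
        z2, p2 = fisher_r_to_z_test(0.2, 70, 0.6, 50)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_tiny_groups_rejected(self):
        with pytest.raises(EvaluationError):
            fisher_r_to_z_test(0.5, 3, 0.2, 50)


class TestResponseLabels:
    def test_percentile_tails_on_uniform_grid(self):
        audrc = pd.Series(np.arange(100, dtype=float),
                          index=[f"s{i}" for i in range(100)])
        labels = label_response_classes(audrc, pct=20)
        assert (labels == "sensitive").sum() == 20
        assert (labels == "resistant").sum() == 20
        assert (labels == "excluded").sum() == 60
        assert set(labels[audrc <= 19].unique()) == {"sensitive"}

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(EvaluationError):
            label_response_classes(pd.Series(np.ones(20)))

    @pytest.mark.parametrize("pct", [0.0, 50.0, 60.0])
    def test_invalid_percentile_rejected(self, pct):
        with pytest.raises(ConfigError):
            label_response_classes(pd.Series(np.arange(20.0)), pct=pct)


class TestPRCurve:
    def test_perfect_separation_has_unit_area(self):
        labels = np.array([True] * 5 + [False] * 5)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        curve = pr_curve(scores, labels)
        assert curve.area == pytest.approx(1.0)
        assert recall_at_precision(curve, 0.95) == pytest.approx(1.0)

    def test_marker_point_counting(self):
        labels = np.zeros(100, dtype=bool)
        labels[:20] = True
        marker = np.zeros(100, dtype=bool)
        marker[:19] = True  # 19 of 20 positives
        marker[50] = True   # 1 negative
        precision, recall = marker_point(marker, labels)
        assert precision == pytest.approx(0.95)
        assert recall == pytest.approx(0.95)

    def test_constant_score_area_near_prevalence(self):
        rng = np.random.default_rng(0)
        labels = rng.random(400) < 0.3
        curve = pr_curve(np.full(400, 0.5), labels)
        assert curve.area == pytest.approx(labels.mean(), abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            pr_curve(np.array([0.1, 0.9]), np.array([True, True]))

    def test_empty_qualifying_set_gives_zero_recall(self):
        labels = np.array([True, False, True, False])
        scores = np.array([0.1, 0.9, 0.2, 0.8])  # anti-correlated
        curve = pr_curve(scores, labels)
        assert recall_at_precision(curve, 0.99) == 0.0


class TestF1:
    @staticmethod
    def _series(flags, classes):
        idx = [f"p{i}" for i in range(len(flags))]
        return pd.Series(flags, index=idx), pd.Series(classes, index=idx)

    def test_perfect_flags(self):
        flags, recist = self._series([1, 1, 0, 0], ["PR", "PR", "SD", "PD"])
        assert f1_eval(flags, recist) == pytest.approx(1.0)

    def test_harmonic_mean_of_half_precision_full_recall(self):
        flags, recist = self._series([1, 1, 1, 1], ["PR", "PR", "SD", "PD"])
        assert f1_eval(flags, recist) == pytest.approx(2 / 3)

    def test_zero_predicted_positives_gives_zero(self):
        flags, recist = self._series([0, 0, 0], ["PR", "SD", "PD"])
        assert f1_eval(flags, recist) == 0.0

    def test_unknown_class_rejected(self):
        flags, recist = self._series([1, 0], ["PR", "CR"])
        with pytest.raises(ValidationError):
            f1_eval(flags, recist)


class TestConcordance:
    def test_perfect_risk_ordering(self):
        months = np.array([1.0, 2.0, 3.0, 4.0])
        risk = np.array([4.0, 3.0, 2.0, 1.0])  # higher risk, shorter survival
        assert concordance(risk, months, np.ones(4, bool)) == pytest.approx(1.0)

    def test_four_patient_worked_example(self):
        months = np.array([2.0, 4.0, 6.0, 8.0])
        risk = np.array([0.9, 0.7, 0.8, 0.1])
        assert concordance(risk, months, np.ones(4, bool)) == pytest.approx(5 / 6)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        months = rng.exponential(10, size=600)
        risk = rng.random(600)
        assert concordance(risk, months, np.ones(600, bool)) == pytest.approx(0.5, abs=0.05)

    def test_all_censored_rejected(self):
        with pytest.raises(EvaluationError):
            concordance(np.array([0.1, 0.2]), np.array([1.0, 2.0]),
                        np.zeros(2, bool))


class TestSurvivalStratify:
    def test_group_summary_and_hazard_direction(self):
        rng = np.random.default_rng(1)
        n = 80
        flags = pd.Series(rng.random(n) < 0.5,
                          index=[f"p{i}" for i in range(n)]).astype(int)
        months = pd.Series(
            np.where(flags == 1, rng.exponential(24, n), rng.exponential(6, n)),
            index=flags.index,
        )
        events = pd.Series(np.ones(n, bool), index=flags.index)
        scores = pd.Series(np.where(flags == 1, 0.3, 0.9), index=flags.index)
        out = survival_stratify(scores, months, events, responder_flags=flags)
        assert out["c_index"] > 0.5
        assert out["hazard_ratio"] < 1.0  # responders at lower hazard
        assert out["median_months"][1] > out["median_months"][0]

    def test_too_small_group_rejected(self):
        idx = [f"p{i}" for i in range(10)]
        flags = pd.Series([1] + [0] * 9, index=idx)
        months = pd.Series(np.arange(1.0, 11.0), index=idx)
        events = pd.Series(np.ones(10, bool), index=idx)
        scores = pd.Series(np.linspace(1, 0, 10), index=idx)
        with pytest.raises(ValidationError):
            survival_stratify(scores, months, events, responder_flags=flags)


class TestClinicalCohort:
    def test_exactly_one_outcome_required(self):
        recist = pd.Series(["PR"], index=["p0"])
        surv = pd.DataFrame({"months": [5.0], "event": [True]}, index=["p0"])
        with pytest.raises(ValidationError):
            ClinicalCohort(mutations=[], recist=recist, survival=surv)
        with pytest.raises(ValidationError):
            ClinicalCohort(mutations=[])
        assert ClinicalCohort(mutations=[], recist=recist).patient_ids == ("p0",)


class TestEnsemblePredict:
    @staticmethod
    def _features(n=4, g=3, c=1):
        rng = np.random.default_rng(0)
        return FeatureMatrix(
            values=rng.random((n, g, c)),
            sample_ids=tuple(f"s{i}" for i in range(n)),
            panel=GenePanel(genes=tuple(f"G{i}" for i in range(g))),
            channel_names=("mutated",)[:c],
        )

    class _Stub:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full(len(X), self.value)

    def test_mean_of_two_models(self):
        feats = self._features()
        preds = ensemble_predict([self._Stub(0.2), self._Stub(0.6)], feats)
        np.testing.assert_allclose(preds.to_numpy(), 0.4)

    def test_model_order_irrelevant(self):
        feats = self._features()
        models = [self._Stub(v) for v in (0.1, 0.5, 0.9)]
        a = ensemble_predict(models, feats)
        b = ensemble_predict(models[::-1], feats)
        pd.testing.assert_series_equal(a, b)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(EvaluationError):
            ensemble_predict([], self._features())


class TestNestedCVIntegrity:
    def test_leaky_plan_rejected(self):
        from qmsdr.evaluate import SplitPlan
        from qmsdr.network import ModelConfig

        rng = np.random.default_rng(0)
        ids = tuple(f"s{i}" for i in range(20))
        feats = FeatureMatrix(
            values=rng.random((20, 2, 1)),
            sample_ids=ids,
            panel=GenePanel(genes=("A", "B")),
            channel_names=("mutated",),
        )
        responses = pd.Series(rng.random(20), index=list(ids))
        leaky = SplitPlan(
            repeats=[{"train": ids[:14], "val": ids[14:17], "test": ids[13:]}],
            fractions=(0.7, 0.15, 0.15), seed=0,
        )
        config = ModelConfig(n_genes=2, n_channels=1,
                             layer_sizes=(2, 2, 2, 2, 2, 2), max_epochs=2)
        with pytest.raises(IntegrityError):
            run_nested_cv(feats, responses, config, leaky)
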