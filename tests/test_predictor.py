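"""Feature construction, ensemble arithmetic, metrics, shuffle robustness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from compmut.composite_caller import call_composites, extract_driver_events
from compmut.io_formats import ValidationError
from compmut.predictor import (
    SHUFFLE_FRACTIONS,
    FeatureMatrices,
    ModelConfig,
    SingleClassError,
    build_feature_matrices,
    ensemble_predict,
    evaluate,
    shuffle_robustness,
    train_ensemble,
    train_model,
)
from compmut.chrom_disruption import normalized_distance

from oracles import auc_pair_counting_oracle


def _feature_fixture(n=300, n_features=8, signal=True, seed=0):
    """Directly constructed feature blocks with (optionally) label-linked
    binary features."""
    rng = np.random.default_rng(seed)
    labels = pd.Series(
        (rng.random(n) < 0.3).astype(int), index=[f"S{i}" for i in range(n)]
    )
    p = np.where(labels.to_numpy()[:, None] == 1, 0.7, 0.1) if signal else 0.2
    binary = pd.DataFrame(
        (rng.random((n, n_features)) < p).astype(int),
        index=labels.index,
        columns=[f"G{j}" for j in range(n_features)],
    )
    dist_values = rng.random(n_features) * 0.5
    distance = pd.DataFrame(
        np.where(binary.to_numpy(dtype=bool), dist_values[None, :], 1.0),
        index=labels.index,
        columns=binary.columns,
    )
    return FeatureMatrices(binary=binary, distance=distance, labels=labels, composite_gene="T")


class TestBuildFeatureMatrices:
    def test_toy_cohort_matches_hand_fixture(self, demo_cohort):
        events = extract_driver_events(demo_cohort)
        calls = call_composites(events, demo_cohort.annotations)
        feats = build_feature_matrices(
            demo_cohort, calls, "BRAF", ["KRAS", "PTEN"], events=events
        )
        # skin tumor type carries the BRAF composite; both skin samples included
        assert set(feats.labels.index) == {"TCGA-BF-A3DL-01", "S-SKIN-004"}
        assert feats.labels["TCGA-BF-A3DL-01"] == 1
        assert feats.labels["S-SKIN-004"] == 0
        # composite sample has KRAS hotspot and PTEN deep deletion
        assert feats.binary.loc["TCGA-BF-A3DL-01"].tolist() == [1, 1]
        assert feats.binary.loc["S-SKIN-004"].tolist() == [0, 0]
        # absent events carry the sentinel distance 1.0
        assert feats.distance.loc["S-SKIN-004"].tolist() == [1.0, 1.0]
        expected_kras = normalized_distance(
            "KRAS", "BRAF", demo_cohort.annotations, demo_cohort.layout
        )
        assert feats.distance.loc["TCGA-BF-A3DL-01", "KRAS"] == pytest.approx(expected_kras)

    def test_target_gene_excluded_from_features(self, demo_cohort):
        events = extract_driver_events(demo_cohort)
        calls = call_composites(events, demo_cohort.annotations)
        feats = build_feature_matrices(
            demo_cohort, calls, "BRAF", ["BRAF", "KRAS"], events=events
        )
        assert "BRAF" not in feats.binary.columns
        assert feats.excluded_features == ["BRAF"]

    def test_empty_feature_list_raises(self, demo_cohort):
        events = extract_driver_events(demo_cohort)
        calls = call_composites(events, demo_cohort.annotations)
        with pytest.raises(ValidationError):
            build_feature_matrices(demo_cohort, calls, "BRAF", ["BRAF"], events=events)


class TestEnsemblePredict:
    def test_weighted_score_hand_arithmetic(self):
        out = ensemble_predict(pd.Series([0.8]), pd.Series([0.4]))
        assert out["score"].iloc[0] == pytest.approx(0.75 * 0.8 + 0.25 * 0.4)
        assert out["predicted"].iloc[0] == 1

    def test_exact_tie_resolves_to_negative(self):
        # 0.75*0.6 + 0.25*0.2 = 0.5 exactly
        out = ensemble_predict(pd.Series([0.6]), pd.Series([0.2]))
        assert out["score"].iloc[0] == pytest.approx(0.5)
        assert out["predicted"].iloc[0] == 0

    def test_degenerate_weights_reduce_to_base_models(self):
        pb = pd.Series([0.9, 0.2, 0.6])
        pdist = pd.Series([0.1, 0.8, 0.4])
        only_binary = ensemble_predict(pb, pdist, ModelConfig(ensemble_weights=(1.0, 0.0)))
        assert (only_binary["score"] == pb).all()
        only_distance = ensemble_predict(pb, pdist, ModelConfig(ensemble_weights=(0.0, 1.0)))
        assert (only_distance["score"] == pdist).all()

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_predict(pd.Series([0.5, 0.5]), pd.Series([0.5]))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1] * 5 + [0] * 5)
        s = np.array([0.9] * 5 + [0.1] * 5)
        cm, rep = evaluate(y, s, (s > 0.5).astype(int))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)
        assert rep.accuracy == rep.balanced_accuracy == rep.auc == 1.0

    def test_closed_form_example(self):
        # TP=3, FP=1, TN=5, FN=1
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        yhat = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        scores = yhat.astype(float)
        cm, rep = evaluate(y, scores, yhat)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 1, 5, 1)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.balanced_accuracy == pytest.approx((3 / 4 + 5 / 6) / 2)
        assert rep.precision == pytest.approx(0.75)
        assert rep.tpr == pytest.approx(0.75)
        assert rep.fpr == pytest.approx(1 / 6)

    def test_single_class_labels_rejected(self):
        y = np.ones(4, dtype=int)
        with pytest.raises(SingleClassError):
            evaluate(y, y.astype(float), y)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        _, rep = evaluate(y, s, (s > 0.5).astype(int))
        assert rep.auc == pytest.approx(auc_pair_counting_oracle(y, s), abs=1e-12)

    def test_auc_invariant_under_monotone_transform_and_flips_with_labels(self):
        rng = np.random.default_rng(3)
        y = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 0])
        s = rng.permutation(np.linspace(0.05, 0.95, 10))  # distinct scores
        _, rep = evaluate(y, s, (s > 0.5).astype(int))
        _, rep2 = evaluate(y, np.exp(4 * s), (s > 0.5).astype(int))
        assert rep2.auc == pytest.approx(rep.auc, abs=1e-12)
        _, rep3 = evaluate(1 - y, s, (s > 0.5).astype(int))
        assert rep3.auc == pytest.approx(1 - rep.auc, abs=1e-12)

    def test_roc_is_step_curve_from_origin_to_one(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        _, rep = evaluate(y, s, (s > 0.5).astype(int))
        roc = rep.roc_points
        assert (roc.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (roc.iloc[-1][["fpr", "tpr"]] == 1).all()
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()


class TestTraining:
    def test_separable_signal_gives_high_auc(self):
        feats = _feature_fixture(signal=True, seed=1)
        result = train_ensemble(feats, ModelConfig(seed=1))
        assert result.report.auc > 0.95

    def test_same_seed_gives_identical_predictions(self):
        feats = _feature_fixture(signal=True, seed=2)
        a = train_ensemble(feats, ModelConfig(seed=7))
        b = train_ensemble(feats, ModelConfig(seed=7))
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_label_permutation_gives_chance_auc(self):
        feats = _feature_fixture(signal=True, seed=3)
        rng = np.random.default_rng(8)
        permuted = FeatureMatrices(
            binary=feats.binary,
            distance=feats.distance,
            labels=pd.Series(
                rng.permutation(feats.labels.to_numpy()), index=feats.labels.index
            ),
            composite_gene="T",
        )
        result = train_ensemble(permuted, ModelConfig(seed=8))
        assert 0.4 <= result.report.auc <= 0.6

    def test_single_class_training_rejected(self):
        feats = _feature_fixture(seed=4)
        ones = pd.Series(1, index=feats.labels.index)
        with pytest.raises(SingleClassError):
            train_model(feats.binary, ones, ModelConfig())

    def test_ensemble_agreement_with_sklearn_auc(self):
        """Trapezoidal step-curve AUC equals the rank-based AUC computed by an
        independent library implementation."""
        feats = _feature_fixture(signal=True, seed=6)
        result = train_ensemble(feats, ModelConfig(seed=6))
        sk = roc_auc_score(result.y_test, result.scores["score"])
        assert result.report.auc == pytest.approx(sk, abs=1e-12)


class TestShuffleRobustness:
    def test_ten_fractions_exactly(self):
        assert SHUFFLE_FRACTIONS == tuple(round(0.1 * k, 1) for k in range(1, 11))
        feats = _feature_fixture(n=150, n_features=5, signal=True, seed=9)
        report = shuffle_robustness(feats, ModelConfig(seed=9), fractions=SHUFFLE_FRACTIONS[:3])
        assert len(report.reports) == 3

    def test_zero_fraction_control_equals_baseline(self):
        feats = _feature_fixture(n=200, n_features=6, signal=True, seed=10)
        config = ModelConfig(seed=10)
        baseline = train_ensemble(feats, config)
        control = shuffle_robustness(feats, config, fractions=(0.0,))
        assert control.reports[0.0].auc == pytest.approx(baseline.report.auc)
        assert control.reports[0.0].accuracy == pytest.approx(baseline.report.accuracy)
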