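"""Band filtering, short-time features, the network ensemble, significance."""

import numpy as np
import pytest

import echonav as en
from echonav.classify import (
    FEATURE_LAYOUT,
    _MLP,
    balanced_accuracy,
    band_split,
    classify_detection,
    dead_end_decision,
    extract_features,
    features_for_recording,
    predict,
    permutation_test,
    train_ensemble,
)
from echonav.config import ClassifyConfig
from echonav.perception import DetectedObject
from echonav.scene import NON_PLANT, PLANT


def tone_recording(freq_hz, sample_rate=250_000.0, n=8750, pose=(0, 0, 0)):
    t = np.arange(n) / sample_rate
    x = np.sin(2 * np.pi * freq_hz * t)
    x[:2500] = 0.0  # pretend the emission interval was already silent
    return en.BinauralRecording(left=x.copy(), right=x.copy(),
                                sample_rate=sample_rate, pose=pose,
                                heading_offset_deg=0.0)


class TestBandSplit:
    def test_six_signals_full_length(self, run_config):
        rec = tone_recording(30_000.0)
        signals = band_split(rec, run_config.sonar)
        assert len(signals) == 6
        assert all(len(s) == rec.n_samples for s in signals)

    def test_tone_lands_in_its_band(self, run_config):
        rec = tone_recording(30_000.0)
        signals = band_split(rec, run_config.sonar)
        energies = [float(np.sum(s**2)) for s in signals]
        # signals ordered (band, ear): 30 kHz belongs to the 20-40 kHz band
        assert energies[0] > 100 * max(energies[2], energies[4])

    def test_zero_signal_passes_through_as_zero(self, run_config):
        rec = en.BinauralRecording(left=np.zeros(8750), right=np.zeros(8750),
                                   sample_rate=250_000.0, pose=(0, 0, 0),
                                   heading_offset_deg=0.0)
        for s in band_split(rec, run_config.sonar):
            assert not np.any(s)


class TestFeatures:
    def test_dimensionality_and_layout(self, run_config):
        rec = tone_recording(30_000.0)
        vec = extract_features(band_split(rec, run_config.sonar)[0], 250_000.0)
        assert vec.shape == (483,)
        assert sum(FEATURE_LAYOUT.values()) == 483
        assert FEATURE_LAYOUT["chroma_vector"] == 299

    def test_constant_signal_has_zero_zcr(self):
        vec = extract_features(np.ones(8750), 250_000.0)
        n = FEATURE_LAYOUT["zcr"]
        assert np.all(vec[:n] == 0.0)

    def test_all_zero_signal_yields_zero_features(self):
        vec = extract_features(np.zeros(8750), 250_000.0)
        assert np.all(vec == 0.0)

    def test_window_count_matches_config(self):
        cfg = ClassifyConfig()
        assert cfg.n_features == 483
        assert cfg.n_windows == 23


class _StubModel:
    """predict() only consumes signal_probs; stub it for vote-rule tests."""

    def __init__(self, probs):
        self._probs = np.asarray(probs, float)

    def signal_probs(self, x6):
        return self._probs


class TestPredictVoting:
    def test_majority_plant(self):
        label, p = predict(_StubModel([0.9, 0.8, 0.7, 0.6, 0.8, 0.1]), None)
        assert label == PLANT
        assert p == pytest.approx(np.mean([0.9, 0.8, 0.7, 0.6, 0.8]))

    def test_majority_non_plant(self):
        label, p = predict(_StubModel([0.1, 0.2, 0.1, 0.3, 0.4, 0.9]), None)
        assert label == NON_PLANT
        assert p == pytest.approx(np.mean([0.9, 0.8, 0.9, 0.7, 0.6]))

    def test_tie_broken_by_mean_sigmoid(self):
        probs = [0.9, 0.9, 0.9, 0.1, 0.2, 0.3]  # 3-3, mean 0.55 -> plant
        label, _ = predict(_StubModel(probs), None)
        assert label == PLANT
        probs = [0.6, 0.6, 0.6, 0.0, 0.0, 0.1]  # 3-3, mean 0.32 -> non-plant
        label, _ = predict(_StubModel(probs), None)
        assert label == NON_PLANT

    def test_unanimous_low_sigmoids(self):
        label, p = predict(_StubModel([0.01] * 6), None)
        assert label == NON_PLANT
        assert p > 0.9


class TestBalancedAccuracy:
    def test_worked_example_from_confusion_rows(self):
        # per-class recalls 77% and 58% average to 67.5% ~ 68%
        labels = [PLANT] * 100 + [NON_PLANT] * 100
        preds = ([PLANT] * 77 + [NON_PLANT] * 23 +
                 [PLANT] * 42 + [NON_PLANT] * 58)
        assert balanced_accuracy(preds, labels) == pytest.approx(0.675)

    def test_perfect_predictions(self):
        labels = [PLANT, NON_PLANT, PLANT]
        assert balanced_accuracy(labels, labels) == 1.0

    def test_constant_predictor_on_imbalanced_set_scores_half(self):
        labels = [PLANT] * 90 + [NON_PLANT] * 10
        preds = [PLANT] * 100
        assert balanced_accuracy(preds, labels) == pytest.approx(0.5)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([PLANT, PLANT], [PLANT, PLANT])


class TestEnsembleTraining:
    def test_architecture_layer_sizes(self):
        net = _MLP(483, (105, 50, 6), dropout=0.5, seed=0)
        assert [w.shape for w in net.W] == [(483, 105), (105, 50), (50, 6), (6, 1)]

    def test_single_class_dataset_rejected(self, run_config):
        X = np.zeros((4, 6, 483))
        with pytest.raises(ValueError, match="both classes"):
            train_ensemble(X, np.ones(4), run_config.classify, seed=0)

    def test_training_is_deterministic(self, echo_classifier, run_config):
        y_all = echo_classifier["y_train"]
        idx = np.concatenate([np.flatnonzero(y_all == 1)[:6],
                              np.flatnonzero(y_all == 0)[:6]])
        X, y = echo_classifier["X_train"][idx], y_all[idx]
        cfg = run_config.classify.model_copy(update={"epochs": 5})
        m1 = train_ensemble(X, y, cfg, seed=3)
        m2 = train_ensemble(X, y, cfg, seed=3)
        x6 = echo_classifier["X_test"][0]
        np.testing.assert_array_equal(m1.signal_probs(x6), m2.signal_probs(x6))

    def test_held_out_accuracy_above_chance(self, echo_classifier):
        assert echo_classifier["balanced_accuracy"] > 0.5


class TestGating:
    def test_far_object_stays_unknown(self, echo_classifier):
        obj = DetectedObject(range_m=3.5, azimuth_deg=0.0, C=0.95)
        x6 = echo_classifier["X_test"][0]
        out = classify_detection(echo_classifier["model"], obj, x6)
        assert out.T == "unknown" and out.P == 0.0

    def test_near_object_is_classified(self, echo_classifier):
        obj = DetectedObject(range_m=1.5, azimuth_deg=0.0, C=0.95)
        x6 = echo_classifier["X_test"][0]
        out = classify_detection(echo_classifier["model"], obj, x6)
        assert out.T in (PLANT, NON_PLANT)
        assert 0.0 <= out.P <= 1.0


class TestDeadEndDecision:
    def _cands(self, probs_by_dir):
        cands = []
        for direction in ("right", "ahead", "left"):
            obj = DetectedObject(range_m=1.0, azimuth_deg=0.0, C=0.95)
            cands.append((direction, obj, probs_by_dir[direction]))
        return cands

    def test_single_plant_chosen(self):
        model = _DirectionalStub({"right": 0.1, "ahead": 0.9, "left": 0.2})
        cands = self._cands({"right": "right", "ahead": "ahead", "left": "left"})
        assert dead_end_decision(cands, model) == "ahead"

    def test_no_plants_is_boxed_in(self):
        model = _DirectionalStub({"right": 0.1, "ahead": 0.2, "left": 0.3})
        cands = self._cands({"right": "right", "ahead": "ahead", "left": "left"})
        assert dead_end_decision(cands, model) == "boxed_in"

    def test_highest_probability_plant_wins(self):
        model = _DirectionalStub({"right": 0.9, "ahead": 0.1, "left": 0.6})
        cands = self._cands({"right": "right", "ahead": "ahead", "left": "left"})
        assert dead_end_decision(cands, model) == "right"

    def test_end_to_end_with_trained_model(self, echo_classifier, run_config):
        # synthesize real echoes from a dead-end layout and classify them
        from echonav.datasets import make_echo_feature_dataset  # noqa: F401
        from echonav.scene import make_dead_end_scene

        scene = make_dead_end_scene("ahead", distance_m=1.2, seed=5)
        cands = []
        for direction, heading in (("right", -90.0), ("ahead", 0.0), ("left", 90.0)):
            sub = [o for o in scene.objects if o.id.endswith(direction)]
            sub_scene = en.Scene(objects=sub, bounds=scene.bounds)
            rec = en.synthesize_echoes(sub_scene, (0, 0, heading), 0.0,
                                       run_config.sonar, seed=13)
            x6 = features_for_recording(rec, run_config.sonar)
            obj = DetectedObject(range_m=1.2, azimuth_deg=0.0, C=0.95)
            cands.append((direction, obj, x6))
        choice = dead_end_decision(cands, echo_classifier["model"])
        assert choice == "ahead"


class _DirectionalStub:
    """Maps feature payloads (direction strings) to fixed sigmoid votes."""

    def __init__(self, prob_by_payload):
        self._p = prob_by_payload

    def signal_probs(self, payload):
        return np.full(6, self._p[payload])


class TestPermutationTest:
    def test_zero_permutations_rejected(self, echo_classifier, run_config):
        with pytest.raises(ValueError):
            permutation_test(echo_classifier["X_train"],
                             echo_classifier["y_train"],
                             echo_classifier["X_test"],
                             echo_classifier["labels_test"],
                             observed_ba=0.9, n_perm=0,
                             config=run_config.classify, seed=0)

    def test_null_distribution_centers_on_chance(self, permutation_result):
        # label permutation destroys the class structure: mean balanced
        # accuracy over permutations sits at 50% (within binomial tolerance)
        _, scores = permutation_result
        assert abs(scores.mean() - 0.5) <= 0.03

    def test_separable_classes_are_significant(self, permutation_result,
                                               echo_classifier):
        p, scores = permutation_result
        assert p <= 0.05
        assert echo_classifier["balanced_accuracy"] > scores.mean()


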