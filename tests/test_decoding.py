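"""Nested leave-one-trial-out decoding and cross-condition generalization."""

import numpy as np
import pandas as pd
import pytest

import mtldecode as m
from mtldecode import svm
from mtldecode.decoding import FoldDegeneracyError
from mtldecode.searchlight import MaskGeometry
from tests.conftest import tiny_config, tiny_geometry


def _separable_problem(mask, n=12, rng=None):
    """Noise-free, linearly separable patterns localized in one cluster."""
    rng = rng or np.random.default_rng(0)
    geom = MaskGeometry(mask, 3)
    X = rng.normal(scale=0.05, size=(n, geom.n_voxels))
    cluster = geom.sphere(geom.n_voxels // 2)[:6]
    labels = np.array(["A", "B"] * (n // 2))
    X[np.ix_(labels == "B", cluster)] += 4.0
    return X, labels


class TestNestedLOOCV:
    def test_noiseless_separable_data_decodes_perfectly(self, ball_mask):
        X, labels = _separable_problem(ball_mask)
        res = m.nested_loocv_decode(X, labels, ball_mask,
                                    m.SearchlightSpec(center_stride=2))
        assert res.accuracy == 1.0

    def test_fold_count_equals_trial_count(self, ball_mask):
        X, labels = _separable_problem(ball_mask, n=14)
        res = m.nested_loocv_decode(X, labels, ball_mask,
                                    m.SearchlightSpec(center_stride=3))
        assert res.n_folds == 14
        assert len(res.folds) == 14
        assert set(res.folds["test_trial"]) == set(range(14))

    def test_single_voxel_roi_reduces_to_plain_loocv(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        roi = m.ROIMask("HC", "L", mask)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 1))
        labels = np.array(["A", "B"] * 8)
        res = m.nested_loocv_decode(X, labels, roi)
        y = np.where(labels == "A", -1, 1).astype(np.int8)
        expected = svm.loo_correct(X @ X.T, y)
        np.testing.assert_array_equal(res.folds["correct"].to_numpy(),
                                      expected.astype(bool))

    def test_leakage_guard_held_out_trial_cannot_steer_selection(self, ball_mask):
        """Replacing the held-out trial's pattern must leave that fold's
        selected feature set and searchlight decision unchanged."""
        rng = np.random.default_rng(2)
        X, labels = _separable_problem(ball_mask, rng=rng)
        spec = m.SearchlightSpec(center_stride=2)
        res1 = m.nested_loocv_decode(X, labels, ball_mask, spec)
        i = 5
        X2 = X.copy()
        X2[i] = rng.normal(scale=10.0, size=X.shape[1])
        res2 = m.nested_loocv_decode(X2, labels, ball_mask, spec)
        assert res1.folds.at[i, "features"] == res2.folds.at[i, "features"]

    def test_leaky_variant_does_use_all_trials(self, ball_mask):
        """The diagnostic all-trials mode *should* react to the held-out
        trial — that contrast is what shows the nesting matters."""
        rng = np.random.default_rng(3)
        n = 12
        X = rng.normal(size=(n, ball_mask.n_voxels))
        labels = np.array(["A", "B"] * (n // 2))
        spec = m.SearchlightSpec(center_stride=2)
        r1 = m.nested_loocv_decode(X, labels, ball_mask, spec,
                                   feature_selection="all-trials")
        sizes1 = set(r1.folds["features"])
        assert len(sizes1) == 1  # one selection shared by all folds

    def test_determinism(self, ball_mask):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, ball_mask.n_voxels))
        labels = np.array(["A", "B"] * 5)
        spec = m.SearchlightSpec(center_stride=3)
        r1 = m.nested_loocv_decode(X, labels, ball_mask, spec)
        r2 = m.nested_loocv_decode(X, labels, ball_mask, spec)
        assert r1.accuracy == r2.accuracy
        assert r1.folds.equals(r2.folds)

    def test_inner_subsampling_still_decodes_separable_data(self, ball_mask):
        X, labels = _separable_problem(ball_mask, n=14)
        spec = m.SearchlightSpec(center_stride=2, inner_subsample=6)
        res = m.nested_loocv_decode(X, labels, ball_mask, spec)
        assert res.accuracy == 1.0
        assert res.n_folds == 14

    def test_degenerate_class_rejected(self, ball_mask):
        X = np.zeros((6, ball_mask.n_voxels))
        with pytest.raises(FoldDegeneracyError):
            m.nested_loocv_decode(X, ["A", "A", "A", "A", "A", "B"], ball_mask)

    def test_accuracy_monotone_in_template_amplitude(self):
        """Median accuracy over seeds is nondecreasing in signal amplitude."""
        amplitudes = [0.3, 0.9, 2.7]
        medians = []
        for amp in amplitudes:
            accs = []
            for seed in range(3):
                cfg = tiny_config(seed=20 + seed, trials_per_condition=8)
                ds = m.simulate_dataset(
                    cfg, geo=tiny_geometry("attractor", amplitude=amp,
                                           noise_sd=1.0))
                model = m.DecodingModel.from_dataset(
                    ds, "HC-L", searchlight=m.SearchlightSpec(center_stride=2))
                accs.append(model.fit("100vs100").accuracy)
            medians.append(float(np.median(accs)))
        assert medians[0] <= medians[1] <= medians[2]
        assert medians[2] > medians[0]


class TestCrossCondition:
    def test_identical_train_test_memorizes(self, ball_mask):
        X, labels = _separable_problem(ball_mask)
        res = m.cross_condition_decode(X, labels, X, labels, ball_mask,
                                       m.SearchlightSpec(center_stride=2))
        assert res.accuracy == 1.0

    def test_voxel_space_mismatch_rejected(self, ball_mask):
        X, labels = _separable_problem(ball_mask)
        with pytest.raises(ValueError, match="voxel space"):
            m.cross_condition_decode(X, labels, X[:, :10], labels, ball_mask)

    def test_attractor_morphs_decode_from_scene_classifier(self):
        cfg = tiny_config(seed=30, trials_per_condition=10)
        ds = m.simulate_dataset(cfg, geo=tiny_geometry("attractor", noise_sd=0.5))
        model = m.DecodingModel.from_dataset(
            ds, "HC-L", searchlight=m.SearchlightSpec(center_stride=2))
        res = model.fit("train100_test50")
        assert res.accuracy > 0.9  # patterns equal chosen-scene templates


class TestMorphGeneralization:
    def test_default_levels_are_the_six_non50_morphs(self):
        cfg = tiny_config(seed=31, trials_per_condition=10)
        ds = m.simulate_dataset(
            cfg, geo=tiny_geometry("intermediate", noise_sd=0.5,
                                   morph_family_correlation=0.9))
        model = m.DecodingModel.from_dataset(
            ds, "HC-L", searchlight=m.SearchlightSpec(center_stride=2))
        res = model.fit("morphgen")
        assert len(res.per_level) == 6
        assert set(res.per_level["level_pct_A"]) == {30, 40, 45, 55, 60, 70}
        # high family correlation -> generalization well above chance
        assert res.accuracy > 0.6

    def test_fifty_excluded_and_empty_levels_rejected(self, ball_mask):
        tt = pd.DataFrame({
            "condition_pct_A": [50.0] * 6 + [60.0] * 4,
            "choice": ["A", "B"] * 5,
        })
        X = np.random.default_rng(5).normal(size=(10, ball_mask.n_voxels))
        with pytest.raises(ValueError, match="exclude"):
            m.morph_generalization(X, tt, ball_mask, test_levels=[50.0])
        with pytest.raises(ValueError, match="level"):
            m.morph_generalization(X, tt, ball_mask, test_levels=[70.0])


class TestModelSurface:
    def test_summary_and_json_round_trip(self, tmp_path, ball_mask):
        X, labels = _separable_problem(ball_mask)
        res = m.nested_loocv_decode(X, labels, ball_mask,
                                    m.SearchlightSpec(center_stride=3))
        text = res.summary()
        assert "Accuracy" in text and "Folds" in text
        path = tmp_path / "res.json"
        res.to_json(path)
        import json
        loaded = json.loads(path.read_text())
        assert loaded["accuracy"] == res.accuracy
        assert loaded["n_folds"] == res.n_folds

    def test_stimulus_labels_exclude_fifty(self, intermediate_dataset):
        model = m.DecodingModel.from_dataset(intermediate_dataset, "HC-L",
                                             label_by="stimulus")
        with pytest.raises(ValueError, match="50"):
            model.fit("50vs50")

    def test_unknown_analysis_rejected(self, attractor_dataset):
        model = m.DecodingModel.from_dataset(attractor_dataset, "HC-L")
        with pytest.raises(ValueError, match="unknown analysis"):
            model.fit("42vs42")
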