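"""Synthetic experiment generator: masks, behavior, templates, datasets."""

import numpy as np
import pytest
from scipy import ndimage

import mtldecode as m
from mtldecode.synth import CapacityError, GeometryError, _morph_template
from tests.conftest import tiny_config, tiny_geometry


class TestMasks:
    def test_requested_counts_met_and_disjoint(self):
        cfg = m.ExperimentConfig(grid_shape=(20, 20, 20),
                                 roi_voxels={"HC": 100, "EC": 25, "PHG": 28},
                                 hemispheres=("L",))
        masks = m.make_roi_masks(cfg)
        union = np.zeros(cfg.grid_shape, dtype=int)
        for name, want in cfg.roi_voxels.items():
            got = masks[f"{name}-L"].n_voxels
            assert abs(got - want) <= 0.1 * want
            union += masks[f"{name}-L"].mask.astype(int)
        assert union.max() == 1  # pairwise disjoint

    def test_masks_are_connected(self):
        cfg = tiny_config()
        for mask in m.make_roi_masks(cfg).values():
            _, n_comp = ndimage.label(mask.mask)
            assert n_comp == 1

    def test_one_voxel_roi(self):
        cfg = m.ExperimentConfig(grid_shape=(8, 8, 8),
                                 roi_voxels={"HC": 1}, hemispheres=("L",))
        masks = m.make_roi_masks(cfg)
        assert masks["HC-L"].n_voxels == 1

    def test_full_scale_hippocampus_count(self):
        # segmentation-scale request: ~1093 voxels within +/-10%
        cfg = m.ExperimentConfig()
        masks = m.make_roi_masks(cfg)
        for hemi in ("L", "R"):
            assert abs(masks[f"HC-{hemi}"].n_voxels - 1093) <= 109

    def test_capacity_error(self):
        cfg = m.ExperimentConfig(grid_shape=(6, 6, 6),
                                 roi_voxels={"HC": 500}, hemispheres=("L",))
        with pytest.raises(CapacityError):
            m.make_roi_masks(cfg)

    def test_hemispheres_do_not_overlap(self):
        cfg = tiny_config(hemispheres=("L", "R"))
        masks = m.make_roi_masks(cfg)
        left = np.zeros(cfg.grid_shape, dtype=bool)
        right = np.zeros(cfg.grid_shape, dtype=bool)
        for label, msk in masks.items():
            if label.endswith("L"):
                left |= msk.mask
            else:
                right |= msk.mask
        assert not np.any(left & right)


class TestBehavior:
    def test_fifty_percent_is_exactly_even(self):
        bm = m.BehaviorModel(bias=50.0, lapse=0.02)
        assert m.psychometric_probability(50.0, bm) == pytest.approx(0.5)

    def test_pure_scene_with_steep_slope_saturates(self):
        bm = m.BehaviorModel(slope=50.0, lapse=0.0)
        assert m.psychometric_probability(100.0, bm) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        assert all(m.simulate_choice(100.0, bm, rng)[0] == "A" for _ in range(50))

    def test_choice_frequency_matches_closed_form(self):
        """60%A, slope 0.2, bias 50, lapse 0.02 over 20,000 draws."""
        bm = m.BehaviorModel(slope=0.2, bias=50.0, lapse=0.02)
        p = float(m.psychometric_probability(60.0, bm))
        rng = np.random.default_rng(1)
        n = 20_000
        hits = sum(m.simulate_choice(60.0, bm, rng)[0] == "A" for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_invalid_lapse_rejected(self):
        with pytest.raises(ValueError):
            m.BehaviorModel(lapse=0.6)
        with pytest.raises(ValueError):
            m.psychometric_probability(120.0, m.BehaviorModel())

    def test_accuracy_monotone_in_distance_from_bias(self):
        """Sigmoid profile: accuracy falls toward the 50% morph (>=5000 trials)."""
        bm = m.BehaviorModel()
        rng = np.random.default_rng(2)
        levels = [100.0, 70.0, 60.0, 55.0]
        acc = []
        for lv in levels:
            n = 1300
            hits = sum(m.simulate_choice(lv, bm, rng)[0] == "A" for _ in range(n))
            acc.append(hits / n)
        assert all(a > b for a, b in zip(acc, acc[1:]))

    def test_rt_rises_and_confidence_falls_toward_ambiguity(self):
        bm = m.BehaviorModel()
        rng = np.random.default_rng(3)
        stats = {}
        for lv in (100.0, 60.0, 50.0):
            draws = [m.simulate_choice(lv, bm, rng) for _ in range(1800)]
            stats[lv] = (np.mean([d[1] for d in draws]),
                         np.mean([d[2] for d in draws]))
        assert stats[100.0][0] < stats[60.0][0] < stats[50.0][0]
        assert stats[100.0][1] > stats[60.0][1] > stats[50.0][1]


class TestTemplates:
    def _mask(self):
        cfg = tiny_config()
        return m.make_roi_masks(cfg)["HC-L"]

    def test_zero_amplitude_templates_identical(self):
        geo = m.GeometrySpec(amplitude=0.0, cluster_radius_voxels=1, n_clusters=2)
        tpl = m.build_templates(self._mask(), geo, np.random.default_rng(0))
        np.testing.assert_array_equal(tpl.A, tpl.B)

    def test_signal_confined_to_clusters(self):
        geo = m.GeometrySpec(amplitude=1.5, cluster_radius_voxels=1, n_clusters=1)
        tpl = m.build_templates(self._mask(), geo, np.random.default_rng(1))
        diff = tpl.A - tpl.B
        outside = np.setdiff1d(np.arange(len(diff)), tpl.cluster_voxels)
        assert np.all(diff[outside] == 0)
        assert np.any(diff[tpl.cluster_voxels] != 0)

    def test_intermediate_family_weakly_correlated_with_scenes(self, ball_mask):
        # radius-2 clusters (~60 voxels) keep the sample correlation of
        # independent draws comfortably below the 0.5 bound
        geo = m.GeometrySpec(mode="intermediate", amplitude=1.0,
                             cluster_radius_voxels=2, n_clusters=2)
        rng = np.random.default_rng(2)
        for _ in range(5):
            tpl = m.build_templates(ball_mask, geo, rng)
            cl = tpl.cluster_voxels
            for fam in tpl.family.values():
                for scene in (tpl.A, tpl.B):
                    r = np.corrcoef(fam[cl], scene[cl])[0, 1]
                    assert abs(r) < 0.5

    def test_cluster_must_fit_inside_roi(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2, 2:6, 2:6] = True  # a 1-voxel-thick sheet
        roi = m.ROIMask("EC", "L", mask)
        geo = m.GeometrySpec(cluster_radius_voxels=2, n_clusters=1)
        with pytest.raises(GeometryError):
            m.build_templates(roi, geo, np.random.default_rng(0))

    def test_morph_templates_share_family_by_construction(self):
        geo = m.GeometrySpec(mode="intermediate", amplitude=1.0,
                             cluster_radius_voxels=1, n_clusters=3,
                             morph_family_correlation=0.9)
        rng = np.random.default_rng(3)
        tpl = m.build_templates(self._mask(), geo, rng)
        t50 = _morph_template(tpl, 50.0, "A", rng)
        t60 = _morph_template(tpl, 60.0, "A", rng)
        cl = tpl.cluster_voxels
        r = np.corrcoef(t50[cl], t60[cl])[0, 1]
        assert r > 0.6  # ~0.9 expected


class TestDataset:
    def test_noiseless_attractor_patterns_equal_templates(self):
        cfg = tiny_config(seed=4)
        ds = m.simulate_dataset(cfg, geo=tiny_geometry("attractor", noise_sd=0.0))
        tpl = ds.templates["HC-L"]
        tt = ds.trial_table
        P = ds.true_patterns["HC-L"]
        for t in np.flatnonzero(tt["condition_pct_A"] == 100.0):
            np.testing.assert_array_equal(P[t], tpl.A)
        # morph trials snap to the chosen scene's template
        for t in np.flatnonzero(tt["condition_pct_A"] == 50.0):
            want = tpl.A if tt.at[t, "choice"] == "A" else tpl.B
            np.testing.assert_array_equal(P[t], want)

    def test_equal_seeds_bitwise_identical(self):
        cfg = tiny_config(seed=5)
        a = m.simulate_dataset(cfg, geo=tiny_geometry())
        b = m.simulate_dataset(cfg, geo=tiny_geometry())
        assert a.trial_table.equals(b.trial_table)
        for k in a.true_patterns:
            np.testing.assert_array_equal(a.true_patterns[k], b.true_patterns[k])

    def test_default_design_has_360_trials(self):
        cfg = m.ExperimentConfig()
        assert cfg.n_trials == 360  # 9 conditions x 40 presentations
        conds = np.repeat([float(c) for c in cfg.conditions],
                          cfg.trials_per_condition)
        assert len(conds) == 360

    def test_trial_table_schema_and_onsets(self, attractor_dataset):
        tt = attractor_dataset.trial_table
        cfg = attractor_dataset.config
        assert len(tt) == cfg.n_trials
        assert set(tt["choice"]) <= {"A", "B"}
        np.testing.assert_allclose(np.diff(tt["onset_s"]), cfg.trial_duration_s)
        assert tt["confidence"].between(1, 3).all()
        assert (tt["rt_s"] > 0).all()

    def test_attractor_choice_means_match_templates_but_intermediate_do_not(self):
        """Grouping 50% trials by choice: in attractor mode the mean pattern
        converges on the chosen 100% template; in intermediate mode it stays
        far from it (correlation gap)."""
        gap_margin = 0.3
        for mode, expect_high in (("attractor", True), ("intermediate", False)):
            cfg = tiny_config(seed=6, trials_per_condition=24)
            ds = m.simulate_dataset(cfg, geo=tiny_geometry(mode, noise_sd=0.3))
            tpl = ds.templates["HC-L"]
            tt = ds.trial_table
            P = ds.true_patterns["HC-L"]
            cl = tpl.cluster_voxels
            rows = np.flatnonzero((tt["condition_pct_A"] == 50.0)
                                  & (tt["choice"] == "A"))
            mean_pat = P[rows].mean(axis=0)
            r = np.corrcoef(mean_pat[cl], tpl.A[cl])[0, 1]
            if expect_high:
                assert r > 0.5 + gap_margin
            else:
                assert r < 0.5

    def test_glm_path_recovers_true_patterns(self):
        cfg = tiny_config(seed=9, trials_per_condition=3)
        ds = m.simulate_dataset(cfg, geo=tiny_geometry(noise_sd=0.2))
        direct = ds.beta_series("HC-L").data
        glm = ds.glm_beta_series("HC-L", bold_noise_sd=0.0).data
        np.testing.assert_allclose(glm, direct, atol=1e-7)
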