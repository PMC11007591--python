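"""Simulator determinism, physics, ground-truth consistency and recovery."""

import numpy as np
import pytest

from crowgaze import gaze_analysis as ga
from crowgaze import kinematics as kin
from crowgaze import synthetic_data as syn
from crowgaze.visual_field import classify_directions, field_metrics
from crowgaze.visual_field import field_model_from_perimetry


class TestObjectPaths:
    def test_seed_determinism(self, reference_model):
        a = syn.simulate_session(reference_model, seed=3, cfg=syn.ScenarioConfig(n_trials=2))
        b = syn.simulate_session(reference_model, seed=3, cfg=syn.ScenarioConfig(n_trials=2))
        np.testing.assert_array_equal(a.target_positions, b.target_positions)
        np.testing.assert_array_equal(
            a.truth.poses.rotations.as_quat(), b.truth.poses.rotations.as_quat()
        )
        np.testing.assert_array_equal(a.markers.markers["m1"], b.markers.markers["m1"])
        c = syn.simulate_session(reference_model, seed=4, cfg=syn.ScenarioConfig(n_trials=2))
        assert not np.array_equal(a.truth.poses.rotations.as_quat(),
                                  c.truth.poses.rotations.as_quat())

    def test_ballistic_arc_apex(self):
        cfg = syn.ScenarioConfig(n_trials=1)
        rng = np.random.default_rng(0)
        time, pos, onsets = syn.simulate_object_path(cfg, 1, rng)
        i2 = int(round(onsets["M2"] * cfg.rate_hz))
        i3 = int(round(onsets["M3"] * cfg.rate_hz))
        arc = pos[i2:i3]
        start = pos[i2 - 1]
        # apex height gain = v_z^2 / (2 g) for the launch vertical speed
        dt = 1.0 / cfg.rate_hz
        vz = (arc[0, 2] - start[2]) / dt + 0.5 * cfg.gravity * dt
        apex_gain = arc[:, 2].max() - start[2]
        assert apex_gain == pytest.approx(vz**2 / (2 * cfg.gravity), abs=0.02)
        # landing on the ground plane
        assert pos[i3][2] == pytest.approx(cfg.landing_ground_m[2], abs=0.05)

    def test_still_segment_is_still(self):
        cfg = syn.ScenarioConfig(n_trials=1)
        time, pos, onsets = syn.simulate_object_path(cfg, 1, np.random.default_rng(1))
        i3 = int(round(onsets["M3"] * cfg.rate_hz)) + 1
        seg = pos[i3 : i3 + int(cfg.still_duration_s * cfg.rate_hz) - 1]
        assert np.ptp(seg, axis=0).max() == 0.0

    def test_wiggle_frequency(self):
        cfg = syn.ScenarioConfig(n_trials=1)
        time, pos, onsets = syn.simulate_object_path(cfg, 1, np.random.default_rng(2))
        i1 = int(round(onsets["M1"] * cfg.rate_hz))
        i2 = int(round(onsets["M2"] * cfg.rate_hz))
        x = pos[i1:i2, 0] - np.mean(pos[i1:i2, 0])
        freqs = np.fft.rfftfreq(len(x), 1 / cfg.rate_hz)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert peak == pytest.approx(cfg.wiggle_frequency_hz, abs=0.1)
        # 2 Hz for 5 s = 10 full cycles
        assert cfg.wiggle_frequency_hz * cfg.wiggle_duration_s == 10.0

    def test_ceiling_scenario_emits_m1_only(self, reference_model):
        cfg = syn.ScenarioConfig(scenario="ceiling_wiggle", n_trials=2)
        sess = syn.simulate_session(reference_model, seed=5, cfg=cfg, render_markers=False)
        assert {e.kind for e in sess.events} == {"M1"}

    def test_arc_outside_room_rejected(self):
        cfg = syn.ScenarioConfig(n_trials=1, throw_flight_s=3.0)  # huge lob
        with pytest.raises(ValueError):
            syn.simulate_object_path(cfg, 1, np.random.default_rng(3))


class TestGroundTruth:
    def test_labels_rederivable_from_poses(self, reference_model):
        sess = syn.simulate_session(
            reference_model, seed=7, cfg=syn.ScenarioConfig(n_trials=2), render_markers=False
        )
        truth = sess.truth
        rel = truth.poses.rotations.inv().apply(
            sess.target_positions - truth.poses.translations
        )
        az = np.degrees(np.arctan2(rel[:, 0], rel[:, 1]))
        el = np.degrees(np.arcsin(rel[:, 2] / np.linalg.norm(rel, axis=1)))
        labels = classify_directions(reference_model, az, el)
        labels = np.where(truth.saccade_mask, "", labels)
        assert (labels == truth.region_labels).all()

    def test_pure_binocular_policy(self, reference_model):
        policy = syn.GazePolicy(
            preferences={
                m: {"binocular": 1.0, "right": 0.0, "left": 0.0}
                for m in ("M1", "M2", "M3", "idle")
            },
            eye_jitter_deg=0.0,
        )
        sess = syn.simulate_session(
            reference_model, seed=8, cfg=syn.ScenarioConfig(n_trials=2),
            policy=policy, render_markers=False,
        )
        keep = ~sess.truth.saccade_mask
        assert (sess.truth.region_labels[keep] == "binocular").all()

    def test_saccade_fraction_in_plausible_band(self, reference_model):
        # observed head-saccade time fraction was of order 10%; the simulator
        # should land in a broad band around it
        fracs = [
            syn.simulate_session(
                reference_model, seed=s, cfg=syn.ScenarioConfig(n_trials=3),
                render_markers=False,
            ).truth.saccade_mask.mean()
            for s in range(3)
        ]
        assert 0.02 < np.mean(fracs) < 0.20

    def test_m3_binocular_preference_sets_expected_score(self, reference_model):
        # P(binocular) = 0.29 for the still phase: expected binocular use
        # score 2p - 1 = -0.42 over many fixations
        policy = syn.GazePolicy(
            preferences={
                "M1": {"binocular": 0.29, "right": 0.355, "left": 0.355},
                "M2": {"binocular": 0.29, "right": 0.355, "left": 0.355},
                "M3": {"binocular": 0.29, "right": 0.355, "left": 0.355},
                "idle": {"binocular": 0.29, "right": 0.355, "left": 0.355},
            },
            pursuit_during_throw=False,
        )
        scores = []
        for seed in range(12):
            sess = syn.simulate_session(
                reference_model, seed=100 + seed,
                cfg=syn.ScenarioConfig(n_trials=5), policy=policy,
                render_markers=False,
            )
            keep = ~sess.truth.saccade_mask
            labs = sess.truth.region_labels[keep]
            B = np.sum(labs == "binocular")
            N = np.sum(labs == "right_monocular_anterior") + np.sum(
                labs == "left_monocular_anterior"
            )
            scores.append((B - N) / (B + N))
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores) - (-0.42)) < 3 * se + 0.02


class TestMarkerRendering:
    def test_noise_free_round_trip(self, reference_model, calibrated_template):
        sess = syn.simulate_session(
            reference_model, seed=9, cfg=syn.ScenarioConfig(n_trials=1),
            template=calibrated_template, noise_mm=0.0, dropout_p=0.0,
        )
        ps = kin.track_poses(sess.markers, calibrated_template)
        assert ps.valid.all()
        err = np.degrees(
            (ps.rotations * sess.truth.poses.rotations.inv()).magnitude()
        ).max()
        assert err < 1e-9

    def test_dropout_fraction(self, reference_model, calibrated_template):
        p = 0.1
        sess = syn.simulate_session(
            reference_model, seed=10, cfg=syn.ScenarioConfig(n_trials=2),
            template=calibrated_template, noise_mm=0.0, dropout_p=p,
        )
        missing = np.mean(
            [np.isnan(xyz[:, 0]).mean() for xyz in sess.markers.markers.values()]
        )
        n = sess.markers.n_frames * len(sess.markers.markers)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(missing - p) < 3 * se

    def test_noise_matches_requested_scale(self, reference_model, calibrated_template):
        sess = syn.simulate_session(
            reference_model, seed=11, cfg=syn.ScenarioConfig(n_trials=1),
            template=calibrated_template, noise_mm=0.5, dropout_p=0.0,
        )
        clean = syn.render_marker_data(
            sess.truth.poses, calibrated_template, 0.0, 0.0, np.random.default_rng(0)
        )
        resid = sess.markers.markers["m1"] - clean.markers["m1"]
        assert np.std(resid) == pytest.approx(0.5, rel=0.05)


class TestSimulatedPerimetry:
    def test_noiseless_round_trip_is_exact(self, reference_model):
        perimetry, axes = syn.simulate_perimetry(
            reference_model, np.random.default_rng(0), azimuth_step_deg=0.0
        )
        model = field_model_from_perimetry(perimetry, axes)
        m0 = field_metrics(reference_model)
        m1 = field_metrics(model)
        assert m1["max_binocular_width_deg"] == pytest.approx(
            m0["max_binocular_width_deg"], abs=1e-9
        )
        assert m1["max_blind_width_deg"] == pytest.approx(
            m0["max_blind_width_deg"], abs=1e-9
        )
        np.testing.assert_allclose(
            model.right_boundary_deg, reference_model.right_boundary_deg, atol=1e-9
        )

    def test_quantized_round_trip_within_one_step(self, reference_model):
        perimetry, axes = syn.simulate_perimetry(
            reference_model, np.random.default_rng(1), azimuth_step_deg=1.0
        )
        model = field_model_from_perimetry(perimetry, axes)
        m0 = field_metrics(reference_model)
        m1 = field_metrics(model)
        assert abs(m1["max_binocular_width_deg"] - m0["max_binocular_width_deg"]) <= 1.0

    def test_eye_movement_span_recovered(self, reference_model):
        span = 16.0
        perimetry, _ = syn.simulate_perimetry(
            reference_model,
            np.random.default_rng(2),
            azimuth_step_deg=0.0,
            eye_movement_span_deg=span,
            n_replicates=12,
        )
        from crowgaze.visual_field import summarize_boundaries

        spans = [
            summarize_boundaries(g["boundary_azimuth_deg"]).span
            for _, g in perimetry.groupby(["eye", "arm_elevation_deg"])
        ]
        # uniform-range oracle: E[max - min] = span (n-1)/(n+1)
        n = 12
        expected = span * (n - 1) / (n + 1)
        assert np.mean(spans) == pytest.approx(expected, abs=1.0)

    def test_diverged_eyes_create_frontal_blind_wedge(self, reference_model):
        perimetry, axes = syn.simulate_perimetry(
            reference_model,
            np.random.default_rng(3),
            condition="away",
            azimuth_step_deg=0.0,
            eye_offset_deg=-30.0,
        )
        model = field_model_from_perimetry(perimetry, axes, condition="away")
        assert model.binocular_width(np.array([16.4]))[0] == 0.0
        m = field_metrics(model)
        # blind maximum moves to the front of the head
        assert -90.0 <= m["max_blind_width_elevation_deg"] <= 90.0
        assert m["max_blind_width_deg"] > 0.0

    def test_thirty_degree_grid(self, reference_model):
        perimetry, _ = syn.simulate_perimetry(
            reference_model, np.random.default_rng(4), elevation_step_deg=30.0
        )
        elevs = np.sort(perimetry["arm_elevation_deg"].unique())
        assert np.allclose(np.diff(elevs), 30.0)


class TestFullPipelineRecovery:
    def test_policy_dwell_recovered_through_marker_pipeline(
        self, reference_model, calibrated_template
    ):
        # a handful of noisy sessions through the complete pipeline: rendered
        # markers -> cleaning -> pose tracking -> saccade filter -> dwell
        p_bino = 0.6
        policy = syn.GazePolicy(
            preferences={
                m: {"binocular": p_bino, "right": 0.2, "left": 0.2}
                for m in ("M1", "M2", "M3", "idle")
            },
            pursuit_during_throw=False,
        )
        recovered, truth_frac = [], []
        for seed in range(6):
            sess = syn.simulate_session(
                reference_model, seed=200 + seed,
                cfg=syn.ScenarioConfig(scenario="ceiling_wiggle", n_trials=3),
                policy=policy, template=calibrated_template,
                noise_mm=0.3, dropout_p=0.02,
            )
            clean = kin.preprocess(sess.markers)
            ps = kin.track_poses(clean, calibrated_template, native_rate=120.0)
            events, mask = kin.detect_saccades(ps)
            ps = ps.with_saccade_mask(mask)
            target = kin.resample_track(sess.time, sess.target_positions, ps.time)
            az, el = ga.target_directions(ps, target)
            d = ga.dwell_by_region(az, el, ps.saccade, reference_model, ps.rate)
            recovered.append(d.seconds["binocular"] / sum(d.seconds.values()))
            keep = ~sess.truth.saccade_mask
            labs = sess.truth.region_labels[keep]
            truth_frac.append(np.mean(labs == "binocular"))
        # the pipeline estimate tracks the simulator truth closely
        np.testing.assert_allclose(recovered, truth_frac, atol=0.05)
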