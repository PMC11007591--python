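"""Field-model construction, classification, areas and chance levels."""

import json

import numpy as np
import pandas as pd
import pytest

from crowgaze import visual_field as vf
from crowgaze.geometry import Direction
from crowgaze.reference_field import (
    reference_field_model,
    reference_model_from_tables,
    reference_perimetry_tables,
)


class TestCorrectViewpoint:
    def test_zero_internodal_distance_is_identity(self):
        assert vf.correct_viewpoint(30.0, 0.0, 280.0) == pytest.approx(30.0)

    def test_infinite_radius_limit(self):
        assert vf.correct_viewpoint(30.0, 12.0, 1e9) == pytest.approx(30.0, abs=1e-6)

    def test_frontal_shift_magnitude(self):
        # planar-triangle closed form at the median plane: atan(d/2 / R)
        shift = vf.correct_viewpoint(0.0, 12.0, 280.0) - 0.0
        assert abs(shift) == pytest.approx(np.degrees(np.arctan(6.0 / 280.0)), abs=1e-9)
        assert abs(shift) == pytest.approx(1.2276, abs=1e-3)

    def test_correction_extends_the_field(self):
        # referenced to the eye (closer to its own side) the boundary sits
        # further across the midline
        assert vf.correct_viewpoint(20.0, 12.0, 280.0) > 20.0
        assert vf.correct_viewpoint(-20.0, 12.0, 280.0) > -20.0

    def test_geometric_impossibility(self):
        with pytest.raises(Exception):
            vf.correct_viewpoint(0.0, 600.0, 280.0)


class TestSummaries:
    def test_max_extent(self):
        s = vf.summarize_boundaries([20.0, 22.0, 24.2])
        assert s.representative == 24.2
        assert s.span == pytest.approx(4.2)
        assert s.n == 3

    def test_single_record(self):
        assert vf.summarize_boundaries([18.0]).representative == 18.0

    def test_strategies(self):
        vals = [10.0, 14.0, 26.0]
        assert vf.summarize_boundaries(vals, "min_extent").representative == 10.0
        assert vf.summarize_boundaries(vals, "median").representative == 14.0

    def test_span_estimates_eye_movement_amplitude(self):
        rng = np.random.default_rng(0)
        obs = 24.0 - rng.uniform(0, 16.0, 200)  # eye retracts the boundary
        s = vf.summarize_boundaries(obs)
        assert s.span == pytest.approx(16.0, abs=1.0)

    def test_empty_raises(self):
        with pytest.raises(vf.MissingDataError):
            vf.summarize_boundaries([])


class TestOpticalAxis:
    def test_median(self):
        recs = [
            vf.OpticalAxisRecord("s", "right", 62.0, -33.0, 1),
            vf.OpticalAxisRecord("s", "right", 63.0, -33.0, 2),
            vf.OpticalAxisRecord("s", "right", 62.7, -32.9, 3),
        ]
        with pytest.warns(UserWarning):
            d = vf.estimate_optical_axis(recs)
        assert d.azimuth == pytest.approx(62.7)
        assert d.elevation == pytest.approx(-33.0)

    def test_single_replicate_is_itself(self):
        with pytest.warns(UserWarning):
            d = vf.estimate_optical_axis([vf.OpticalAxisRecord("s", "left", 59.4, -33.8, 1)])
        assert (d.azimuth, d.elevation) == (59.4, -33.8)

    def test_symmetric_noise_recovers_truth(self):
        rng = np.random.default_rng(1)
        n = 99
        recs = pd.DataFrame(
            {
                "azimuth_deg": 60.0 + rng.normal(0, 2.0, n),
                "elevation_deg": -30.0 + rng.normal(0, 2.0, n),
            }
        )
        d = vf.estimate_optical_axis(recs)
        # median s.e. ~ 1.25 sigma/sqrt(n); allow 4x
        assert d.azimuth == pytest.approx(60.0, abs=1.0)
        assert d.elevation == pytest.approx(-30.0, abs=1.0)

    def test_empty_raises(self):
        with pytest.raises(vf.MissingDataError):
            vf.estimate_optical_axis([])


def _toy_boundaries(cross: float) -> pd.DataFrame:
    rows = []
    for eye in ("left", "right"):
        for phi, b in ((0.0, cross), (10.0, cross), (180.0, -5.0), (190.0, -5.0)):
            rows.append(
                {"eye": eye, "arm_elevation_deg": phi, "boundary_azimuth_deg": b}
            )
    return pd.DataFrame(rows)


_TOY_AXES = {"right": Direction(62.7, -32.9), "left": Direction(-59.4, -33.8)}


class TestBuildFieldModel:
    def test_symmetric_crossing_gives_doubled_width(self):
        model = vf.build_field_model(_toy_boundaries(24.2), _TOY_AXES)
        m = vf.field_metrics(model)
        assert m["max_binocular_width_deg"] == pytest.approx(48.4)

    def test_negative_crossing_gives_frontal_blind_wedge(self):
        # diverged eyes: no binocular field, a blind area in front instead
        model = vf.build_field_model(_toy_boundaries(-8.0), _TOY_AXES)
        assert model.binocular_width(np.array([5.0]))[0] == 0.0
        lab = vf.classify_direction(model, Direction(0.0, 5.0))
        assert lab == "blind"

    def test_too_few_elevations(self):
        df = _toy_boundaries(20.0).iloc[:1]
        with pytest.raises(vf.InsufficientDataError):
            vf.build_field_model(df, _TOY_AXES)

    def test_contradictory_duplicates_rejected(self):
        df = pd.concat([_toy_boundaries(20.0)] * 2, ignore_index=True)
        with pytest.raises(vf.InvalidInputError):
            vf.build_field_model(df, _TOY_AXES)

    def test_gap_fill_interpolates_and_flags(self):
        df = _toy_boundaries(20.0)
        df.loc[
            (df.eye == "left") & (df.arm_elevation_deg == 10.0), "boundary_azimuth_deg"
        ] = np.nan
        df = df.dropna()
        model = vf.build_field_model(df, _TOY_AXES)
        i = int(np.flatnonzero(model.phi_deg == 10.0 + 0.0)[0])
        assert model.left_fill[i]
        assert not model.right_fill[i]
        assert np.isfinite(model.left_boundary_deg[i])

    def test_calibration_shifts_elevations(self):
        model = vf.build_field_model(
            _toy_boundaries(24.2), _TOY_AXES, beak_elevation_measured=-6.4
        )
        # pitch about the inter-eye axis: arm elevations shift by -3.6
        assert model.phi_deg[0] == pytest.approx(0.0 - 3.6)
        assert model.beak_projection.elevation == -10.0


class TestClassification:
    def test_published_landmark_directions(self, reference_model):
        m = reference_model
        assert vf.classify_direction(m, m.beak_projection) == "binocular"
        assert vf.classify_direction(m, Direction(180.0, 4.0)) == "blind"
        assert (
            vf.classify_direction(m, m.optical_axis_right)
            == "right_monocular_anterior"
        )
        assert (
            vf.classify_direction(m, m.optical_axis_left) == "left_monocular_anterior"
        )

    def test_every_direction_gets_exactly_one_label(self, reference_model):
        rng = np.random.default_rng(3)
        az = rng.uniform(-180, 180, 5000)
        el = rng.uniform(-90, 90, 5000)
        labels = vf.classify_directions(reference_model, az, el)
        assert set(np.unique(labels)) <= set(vf.REGION_LABELS)
        assert not np.any(labels == "")

    def test_pecten_only_when_requested(self, reference_model):
        from crowgaze.geometry import vector_from_arm, directions_from_vectors

        v = vector_from_arm(np.array(116.4), np.array(53.0))  # inside right wedge
        az, el = directions_from_vectors(v.reshape(1, 3))
        with_p = vf.classify_directions(reference_model, az, el, include_pecten=True)
        without = vf.classify_directions(reference_model, az, el, include_pecten=False)
        assert with_p[0] == "pecten"
        assert without[0] == "right_monocular_posterior"

    def test_consistent_with_field_metrics(self, reference_model):
        m = vf.field_metrics(reference_model)
        phi = m["max_binocular_width_elevation_deg"]
        # a midline direction at the max-binocular elevation classifies binocular
        from crowgaze.geometry import vector_from_arm, directions_from_vectors

        v = vector_from_arm(np.array(phi), np.array(0.0))
        az, el = directions_from_vectors(v.reshape(1, 3))
        assert vf.classify_directions(reference_model, az, el)[0] == "binocular"


class TestAreasAndChance:
    def test_region_areas_sum_to_sphere(self, reference_model):
        a = vf.region_areas(reference_model)
        assert sum(a.values()) == pytest.approx(4 * np.pi, abs=1e-6)

    def test_map_mode_sums_to_map(self, reference_model):
        a = vf.region_areas(reference_model, weighting="map")
        assert sum(a.values()) == pytest.approx(360.0 * 180.0, rel=1e-9)

    def test_areas_match_monte_carlo_classification(self, reference_model):
        # independent route: classify uniform random directions on the sphere
        # and compare label fractions with the analytic boundary integrals
        rng = np.random.default_rng(7)
        n = 400_000
        z = rng.uniform(-1.0, 1.0, n)
        az = rng.uniform(-180.0, 180.0, n)
        el = np.degrees(np.arcsin(z))
        labels = vf.classify_directions(reference_model, az, el)
        areas = vf.region_areas(reference_model)
        for region, omega in areas.items():
            frac_mc = float(np.mean(labels == region))
            frac_an = omega / (4 * np.pi)
            se = np.sqrt(frac_an * (1 - frac_an) / n)
            assert abs(frac_mc - frac_an) < 4 * se + 1e-4, region

    def test_mirror_symmetric_laterality_chance_is_exact_zero(self, reference_model):
        sym = vf.mirror_symmetrize(reference_model)
        assert vf.chance_levels(sym)["laterality_chance"] == 0.0

    def test_monotonicity_of_binocular_chance(self, reference_model):
        base = vf.chance_levels(reference_model)["binocular_use_chance"]
        bigger = reference_model.copy()
        bigger.right_boundary_deg = bigger.right_boundary_deg + 2.0
        bigger.left_boundary_deg = bigger.left_boundary_deg + 2.0
        assert vf.chance_levels(bigger)["binocular_use_chance"] > base

    def test_zero_area_raises(self):
        grid = np.arange(-83.6, 266.5, 10.0)
        b = np.full(grid.size, -90.0)
        model = vf.VisualFieldModel(
            phi_deg=grid,
            right_boundary_deg=b,
            left_boundary_deg=b,
            right_fill=np.zeros(grid.size, bool),
            left_fill=np.zeros(grid.size, bool),
            optical_axis_right=Direction(60.0, -30.0),
            optical_axis_left=Direction(-60.0, -30.0),
        )
        with pytest.raises(vf.UndefinedScoreError):
            vf.chance_levels(model)


class TestSerialization:
    def test_bit_exact_round_trip(self, reference_model):
        text = reference_model.to_json()
        back = vf.VisualFieldModel.from_json(text)
        np.testing.assert_array_equal(back.phi_deg, reference_model.phi_deg)
        np.testing.assert_array_equal(
            back.right_boundary_deg, reference_model.right_boundary_deg
        )
        np.testing.assert_array_equal(
            back.left_boundary_deg, reference_model.left_boundary_deg
        )
        assert back.optical_axis_right == reference_model.optical_axis_right
        assert back.to_json() == text

    def test_rejects_foreign_json(self):
        with pytest.raises(vf.InvalidInputError):
            vf.VisualFieldModel.from_json(json.dumps({"format": "other"}))


class TestTablePipeline:
    def test_fixture_tables_reproduce_packaged_model(self, reference_model, tmp_path):
        perimetry, axes = reference_perimetry_tables()
        pfile, afile = tmp_path / "perimetry.csv", tmp_path / "axes.csv"
        perimetry.to_csv(pfile, index=False)
        axes.to_csv(afile, index=False)
        model = vf.field_model_from_perimetry(
            vf.read_perimetry(pfile), vf.read_optical_axes(afile)
        )
        np.testing.assert_array_equal(model.phi_deg, reference_model.phi_deg)
        np.testing.assert_array_equal(
            model.right_boundary_deg, reference_model.right_boundary_deg
        )
        assert model.optical_axis_left == reference_model.optical_axis_left
        assert model.pecten_right is not None

    def test_missing_columns_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        pd.DataFrame({"foo": [1]}).to_csv(f, index=False)
        with pytest.raises(vf.InvalidInputError):
            vf.read_perimetry(f)

    def test_published_metrics_from_tables(self):
        model = reference_model_from_tables()
        m = vf.field_metrics(model)
        assert m["max_binocular_width_deg"] == pytest.approx(48.4, abs=1e-9)
        assert m["max_blind_width_deg"] == pytest.approx(17.1, abs=1e-9)

    def test_cli_build_field(self, tmp_path):
        from click.testing import CliRunner

        from crowgaze.cli import main

        perimetry, axes = reference_perimetry_tables()
        pfile, afile = tmp_path / "p.csv", tmp_path / "a.csv"
        perimetry.to_csv(pfile, index=False)
        axes.to_csv(afile, index=False)
        out = tmp_path / "model.json"
        runner = CliRunner()
        res = runner.invoke(
            main,
            [
                "build-field",
                "--perimetry", str(pfile),
                "--optical-axes", str(afile),
                "--out", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        model = vf.VisualFieldModel.from_json(out.read_text())
        assert vf.field_metrics(model)["max_binocular_width_deg"] == pytest.approx(48.4)
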