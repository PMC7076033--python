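"""Ground-truth properties of the synthetic generators."""
import numpy as np
import pytest

from osteoorient.dynamics import cdi
from osteoorient.errors import PlacementError, ValidationError
from osteoorient.morphology import eccentricity
from osteoorient.synthetic import (
    CellPopulationSpec,
    FiberFieldSpec,
    ScenarioLabel,
    make_cell_masks,
    make_deforming_masks,
    make_fiber_texture,
    make_tracks,
    scenario_specs,
)


def circular_mean_axial(deg):
    """Mean of axial (180-periodic) angles in degrees."""
    doubled = np.radians(2 * np.asarray(deg))
    return (np.degrees(np.arctan2(np.sin(doubled).mean(),
                                  np.cos(doubled).mean())) / 2) % 180


class TestFiberTexture:
    def test_deterministic_under_seed(self):
        spec = FiberFieldSpec(width_px=128, n_fibers=200, seed=9)
        a = make_fiber_texture(spec).pixels
        b = make_fiber_texture(spec).pixels
        assert np.array_equal(a, b)

    def test_distinct_seeds_distinct_images(self):
        a = make_fiber_texture(FiberFieldSpec(width_px=128, seed=1)).pixels
        b = make_fiber_texture(FiberFieldSpec(width_px=128, seed=2)).pixels
        assert not np.array_equal(a, b)

    def test_no_fibers_gives_background_only(self):
        img = make_fiber_texture(
            FiberFieldSpec(width_px=128, n_fibers=0, background_noise_sd=0.0)
        )
        assert np.all(img.pixels == 0)

    def test_values_in_unit_interval(self):
        img = make_fiber_texture(FiberFieldSpec(width_px=128, seed=3))
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    @pytest.mark.parametrize("mean_deg", [0.0, 30.0, 111.0])
    def test_orientation_recovery_at_high_concentration(self, mean_deg):
        spec = FiberFieldSpec(
            width_px=128, mean_orientation_deg=mean_deg, concentration=20.0, seed=6
        )
        angles = make_fiber_texture(spec).meta["fiber_orientations_deg"]
        diff = abs(circular_mean_axial(angles) - mean_deg)
        assert min(diff, 180 - diff) < 3.0

    def test_zero_concentration_orientations_uniform(self):
        spec = FiberFieldSpec(width_px=128, concentration=0.0, n_fibers=4000, seed=2)
        angles = np.asarray(make_fiber_texture(spec).meta["fiber_orientations_deg"])
        # resultant length of doubled angles ~ 1/sqrt(n) for uniform data
        doubled = np.radians(2 * angles)
        resultant = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
        assert resultant < 0.05
        hist, _ = np.histogram(angles, bins=18, range=(0, 180))
        assert hist.min() > 0.5 * hist.mean()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            FiberFieldSpec(width_px=32)
        with pytest.raises(ValidationError):
            FiberFieldSpec(concentration=-1.0)
        with pytest.raises(ValidationError):
            FiberFieldSpec(mean_orientation_deg=180.0)


class TestCellMasks:
    def test_circle_population_measures_round(self):
        spec = CellPopulationSpec(
            n_cells=5, eccentricity=0.0, orientation_deg=0.0,
            mean_area_px=1257.0, seed=1,
        )
        mask = make_cell_masks(spec, 512)
        for lab in mask.label_ids():
            assert eccentricity(mask, int(lab)).eccentricity < 0.1

    def test_programmed_eccentricity_recovered(self):
        spec = CellPopulationSpec(
            n_cells=5, eccentricity=0.961, orientation_deg=45.0,
            mean_area_px=1257.0, seed=2,
        )
        mask = make_cell_masks(spec, 512)
        for lab in mask.label_ids():
            shape = eccentricity(mask, int(lab))
            assert shape.area_px >= 500
            assert shape.eccentricity == pytest.approx(0.961, abs=0.02)

    def test_match_fibers_orientation(self):
        spec = CellPopulationSpec(
            n_cells=1, eccentricity=0.9, orientation_deg="match_fibers",
            mean_area_px=1257.0, seed=3,
        )
        mask = make_cell_masks(spec, 256, fiber_orientation_deg=30.0)
        diff = abs(eccentricity(mask, 1).orientation_deg - 30.0)
        assert min(diff, 180 - diff) < 3.0

    def test_match_fibers_without_direction_rejected(self):
        spec = CellPopulationSpec(orientation_deg="match_fibers")
        with pytest.raises(ValidationError):
            make_cell_masks(spec, 256)

    def test_labels_sequential_and_disjoint(self):
        spec = CellPopulationSpec(n_cells=8, eccentricity=0.5, seed=4)
        mask = make_cell_masks(spec, 512)
        assert list(mask.label_ids()) == list(range(1, 9))

    def test_impossible_placement_raises(self):
        spec = CellPopulationSpec(n_cells=30, eccentricity=0.0,
                                  mean_area_px=1257.0, seed=5)
        with pytest.raises(PlacementError):
            make_cell_masks(spec, 96)

    def test_deterministic(self):
        spec = CellPopulationSpec(n_cells=4, eccentricity=0.7, seed=11)
        assert np.array_equal(
            make_cell_masks(spec, 256).labels, make_cell_masks(spec, 256).labels
        )


class TestTracks:
    def test_zero_speed_points_coincide(self):
        ts = make_tracks(3, speed_um_min=0.0, n_steps=5, seed=1)
        for tid in ts.track_ids():
            pts = ts.points(tid)
            assert np.all(pts[:, 1] == pts[0, 1])
            assert np.all(pts[:, 2] == pts[0, 2])

    def test_straight_track_path_length(self):
        ts = make_tracks(1, speed_um_min=0.5, step_min=10.0, n_steps=6,
                         turn_sd_deg=0.0, seed=2)
        pts = ts.points(1)
        steps = np.hypot(np.diff(pts[:, 1]), np.diff(pts[:, 2]))
        assert steps.sum() == pytest.approx(0.5 * 10 * 6, rel=1e-12)
        # no turning: net displacement equals path length
        net = np.hypot(pts[-1, 1] - pts[0, 1], pts[-1, 2] - pts[0, 2])
        assert net == pytest.approx(steps.sum(), rel=1e-9)

    def test_sampling_grid(self):
        ts = make_tracks(2, 0.3, step_min=10.0, n_steps=18, seed=3)
        pts = ts.points(1)
        assert pts.shape[0] == 19
        assert np.array_equal(pts[:, 0], np.arange(19) * 10.0)

    def test_deterministic(self):
        a = make_tracks(4, 0.4, seed=7).frame
        b = make_tracks(4, 0.4, seed=7).frame
        assert a.equals(b)


class TestDeformingMasks:
    @pytest.fixture
    def base(self):
        spec = CellPopulationSpec(n_cells=4, eccentricity=0.5,
                                  mean_area_px=800.0, seed=6)
        return make_cell_masks(spec, 512)

    def test_level_zero_identical(self, base):
        t0, t1 = make_deforming_masks(base, 0.0, seed=1)
        assert np.array_equal(t0.labels, t1.labels)
        for lab in base.label_ids():
            assert cdi(t0, t1, int(lab)).cdi == 0.0

    def test_level_one_disjoint(self, base):
        t0, t1 = make_deforming_masks(base, 1.0, seed=1)
        for lab in base.label_ids():
            assert cdi(t0, t1, int(lab)).cdi == 1.0

    def test_intermediate_level_strictly_between(self, base):
        t0, t1 = make_deforming_masks(base, 0.5, seed=7)
        for lab in base.label_ids():
            assert 0.0 < cdi(t0, t1, int(lab)).cdi < 1.0

    def test_area_preserved(self, base):
        t0, t1 = make_deforming_masks(base, 0.5, seed=2)
        for lab in base.label_ids():
            assert np.count_nonzero(t1.labels == lab) == np.count_nonzero(
                t0.labels == lab
            )


class TestScenarios:
    def test_labels_validated(self):
        with pytest.raises(ValidationError):
            ScenarioLabel("day15like")

    def test_stage_contrast_encoded(self):
        f10, c10 = scenario_specs("day10like", 1)
        f21, c21 = scenario_specs("day21like", 1)
        assert f10.concentration > 20 and f21.concentration == 0
        assert c10.eccentricity > c21.eccentricity
        assert c10.orientation_deg == "match_fibers"
        assert c21.orientation_deg == "random"
        # same seed, same mean orientation baseline
        assert f10.mean_orientation_deg == f21.mean_orientation_deg
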