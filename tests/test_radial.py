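"""Radial pipeline: cell-mask construction, segmentation, speckle
enhancement, vesicle identification and distance-to-centroid statistics."""

import numpy as np
import pandas as pd
import pytest

from ccvtrack.radial import (
    CellObject,
    corrected_distance,
    distance_to_centroid,
    enhance_speckles,
    fraction_at_distance,
    identify_vesicles,
    make_cell_mask,
    max_projection,
    radial_pipeline,
    segment_cells,
)
from ccvtrack.simulate import OpticsModel, make_cell_scene


def disk_image(shape, cx, cy, radius, value=25.0, background=0.0):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, float(background))
    img[(xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2] = value
    return img


def make_cell(shape, cx, cy, radius, label=1):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    return CellObject(label=label, mask=mask, area=float(mask.sum()),
                      centroid=(float(cx), float(cy)), border_touching=False)


class TestMakeCellMask:
    def test_constant_image_all_zero(self):
        out = make_cell_mask(np.full((64, 64), 9.0), ball_radius=15)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_disk_becomes_smooth_blob(self):
        img = disk_image((128, 128), 64, 64, 20, value=45.0)
        out = make_cell_mask(img, ball_radius=50)
        assert out[64, 64] > 0.9            # plateau saturates the [3, 30] window
        assert out[5, 5] < 0.05
        # blur keeps a single smooth maximum
        assert out.max() == out[60:69, 60:69].max()

    def test_two_disjoint_disks_stay_disjoint(self):
        img = disk_image((128, 128), 32, 64, 18) + disk_image((128, 128), 96, 64, 18)
        out = make_cell_mask(img, ball_radius=40)
        assert out[64, 32] > 0.5 and out[64, 96] > 0.5
        assert out[64, 64] < 0.2

    def test_max_projection_flattens_stack(self):
        stack = np.stack([np.zeros((8, 8)), np.full((8, 8), 3.0)])
        np.testing.assert_array_equal(max_projection(stack), 3.0)


class TestSegmentCells:
    def test_single_disk_geometry(self):
        img = make_cell_mask(disk_image((192, 192), 90, 96, 50, value=45.0),
                             ball_radius=150)
        cells = segment_cells(img)
        retained = [c for c in cells if not c.border_touching]
        assert len(retained) == 1
        cell = retained[0]
        assert cell.area == pytest.approx(np.pi * 50**2, rel=0.03)
        assert cell.centroid[0] == pytest.approx(90, abs=1.0)
        assert cell.centroid[1] == pytest.approx(96, abs=1.0)

    def test_border_touching_cell_flagged(self):
        img = disk_image((128, 128), 10, 64, 30)
        cells = segment_cells(img)
        assert all(c.border_touching for c in cells)

    def test_two_separated_disks(self):
        img = disk_image((160, 160), 48, 80, 25) + disk_image((160, 160), 115, 80, 25)
        cells = segment_cells(img)
        assert len([c for c in cells if not c.border_touching]) == 2

    def test_constant_image_zero_objects(self):
        assert segment_cells(np.full((32, 32), 4.0)) == []


class TestEnhanceSpeckles:
    def test_constant_image_zeroed(self):
        np.testing.assert_allclose(enhance_speckles(np.full((32, 32), 8.0)), 0.0)

    def test_small_spots_kept_gradient_removed(self):
        h, w = 100, 100
        grad = np.linspace(0, 50, w)[None, :].repeat(h, axis=0)
        ys, xs = np.mgrid[0:h, 0:w]
        spots = 40.0 * np.exp(-((xs - 30) ** 2 + (ys - 50) ** 2) / (2 * 1.5**2))
        out = enhance_speckles(grad + spots, feature_size=20)
        assert out[50, 30] >= 0.9 * 40.0
        assert abs(out[20, 70]) < 4.0      # plain gradient region suppressed

    def test_large_blob_suppressed(self):
        img = disk_image((128, 128), 64, 64, 20, value=50.0)   # 40 px wide
        out = enhance_speckles(img, feature_size=20)
        assert out[64, 64] < 0.1 * 50.0


class TestIdentifyVesicles:
    def test_single_spot_assigned_to_parent(self):
        shape = (128, 128)
        cell = make_cell(shape, 64, 64, 40)
        ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
        enhanced = 50.0 * np.exp(-((xs - 70) ** 2 + (ys - 60) ** 2) / (2 * 2.0**2))
        ves = identify_vesicles(enhanced, [cell])
        assert len(ves) == 1
        assert ves.iloc[0].parent_label == 1
        assert ves.iloc[0].x == pytest.approx(70, abs=0.5)
        assert ves.iloc[0].y == pytest.approx(60, abs=0.5)

    def test_two_well_separated_spots(self):
        shape = (128, 128)
        cell = make_cell(shape, 64, 64, 45)
        ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
        enhanced = sum(
            50.0 * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * 2.0**2))
            for x0, y0 in [(50, 64), (80, 64)]
        )
        assert len(identify_vesicles(enhanced, [cell])) == 2

    def test_clump_split_at_two_intensity_peaks(self):
        shape = (128, 128)
        cell = make_cell(shape, 64, 64, 45)
        ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
        enhanced = sum(
            50.0 * np.exp(-((xs - x0) ** 2 + (ys - 64) ** 2) / (2 * 2.0**2))
            for x0 in (61, 67)   # 6 px apart: overlapping but two peaks
        )
        ves = identify_vesicles(enhanced, [cell])
        assert len(ves) == 2

    def test_border_cells_excluded(self):
        shape = (128, 128)
        cell = make_cell(shape, 64, 64, 40)
        cell.border_touching = True
        enhanced = np.zeros(shape)
        enhanced[64, 64] = 50.0
        assert len(identify_vesicles(enhanced, [cell])) == 0


class TestDistances:
    def test_euclidean_distance_example(self):
        cell = make_cell((128, 128), 50, 50, 45)
        ves = pd.DataFrame({"parent_label": [1], "x": [60.0], "y": [50.0]})
        out = distance_to_centroid(ves, [cell])
        assert out.iloc[0].distance == pytest.approx(10.0)
        assert cell.mean_child_distance == pytest.approx(10.0)

    def test_cell_without_children_mean_is_nan(self):
        cell = make_cell((64, 64), 32, 32, 20)
        out = distance_to_centroid(
            pd.DataFrame(columns=["parent_label", "x", "y"]), [cell])
        assert len(out) == 0
        assert np.isnan(cell.mean_child_distance)

    def test_translation_and_rotation_invariance(self):
        shape = (160, 160)
        pts = [(70.0, 60.0), (90.0, 95.0), (64.0, 80.0)]
        cell_a = make_cell(shape, 80, 80, 40)
        va = distance_to_centroid(
            pd.DataFrame([(1, x, y) for x, y in pts],
                         columns=["parent_label", "x", "y"]), [cell_a])
        # translate by (+15, -10)
        cell_b = make_cell(shape, 95, 70, 40)
        vb = distance_to_centroid(
            pd.DataFrame([(1, x + 15, y - 10) for x, y in pts],
                         columns=["parent_label", "x", "y"]), [cell_b])
        np.testing.assert_allclose(vb["distance"], va["distance"], atol=1e-9)
        # rotate 90° about the centroid
        vc = distance_to_centroid(
            pd.DataFrame([(1, 80 - (y - 80), 80 + (x - 80)) for x, y in pts],
                         columns=["parent_label", "x", "y"]), [cell_a])
        np.testing.assert_allclose(np.sort(vc["distance"]),
                                   np.sort(va["distance"]), atol=1e-9)


class TestCorrectedDistance:
    def test_dimensionless_mode_value(self):
        cell = make_cell((64, 64), 32, 32, 20)
        cell.area = 400.0
        cell.mean_child_distance = 10.0
        assert corrected_distance(cell) == pytest.approx(0.5)

    def test_scale_invariance_of_dimensionless_mode(self):
        small = make_cell((64, 64), 32, 32, 10)
        small.mean_child_distance = 6.0
        big = make_cell((128, 128), 64, 64, 20)
        big.mean_child_distance = 12.0
        # mask-derived areas scale by ~4, distances by 2
        assert corrected_distance(big) == pytest.approx(
            corrected_distance(small), rel=0.02)

    def test_literal_mode_collapses_to_sqrt_area_with_warning(self):
        cell = make_cell((64, 64), 32, 32, 20)
        cell.area = 400.0
        cell.mean_child_distance = 10.0
        with pytest.warns(UserWarning):
            assert corrected_distance(cell, "literal") == pytest.approx(20.0)

    def test_undefined_without_children(self):
        cell = make_cell((64, 64), 32, 32, 20)
        with pytest.raises(ValueError):
            corrected_distance(cell)


class TestFractionAtDistance:
    def test_outer_ring_placement(self):
        cell = make_cell((128, 128), 64, 64, 40)
        r = 0.9 * cell.max_radius
        ves = pd.DataFrame({
            "parent_label": 1,
            "x": 64 + r * np.cos(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
            "y": 64 + r * np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
        })
        ves = distance_to_centroid(ves, [cell])
        np.testing.assert_allclose(fraction_at_distance(ves, cell), [0, 0, 0, 1])

    def test_all_at_centroid(self):
        cell = make_cell((128, 128), 64, 64, 40)
        ves = distance_to_centroid(
            pd.DataFrame({"parent_label": [1] * 5, "x": [64.0] * 5,
                          "y": [64.0] * 5}), [cell])
        np.testing.assert_allclose(fraction_at_distance(ves, cell), [1, 0, 0, 0])

    def test_uniform_disk_fractions_proportional_to_annulus_area(self):
        rng = np.random.default_rng(5)
        cell = make_cell((256, 256), 128, 128, 100)
        n = 40_000
        r = cell.max_radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        ves = distance_to_centroid(
            pd.DataFrame({"parent_label": 1, "x": 128 + r * np.cos(th),
                          "y": 128 + r * np.sin(th)}), [cell])
        fracs = fraction_at_distance(ves, cell)
        np.testing.assert_allclose(fracs, np.array([1, 3, 5, 7]) / 16, atol=0.01)

    def test_fractions_sum_to_one(self):
        cell = make_cell((128, 128), 64, 64, 40)
        rng = np.random.default_rng(6)
        ves = distance_to_centroid(
            pd.DataFrame({"parent_label": 1,
                          "x": 64 + rng.uniform(-25, 25, 30),
                          "y": 64 + rng.uniform(-25, 25, 30)}), [cell])
        fracs = fraction_at_distance(ves, cell, n_bins=6)
        assert fracs.sum() == pytest.approx(1.0)
        assert ((fracs >= 0) & (fracs <= 1)).all()


class TestEndToEnd:
    def test_ring_scene_recovers_mean_distance(self):
        optics = OpticsModel(image_shape=(192, 192), background=2.0,
                             amplitude=60.0, read_noise_sigma=1.0,
                             poisson_noise=True)
        cell_img, ves_img, truth = make_cell_scene(
            55, 40, "ring:30", optics, seed=20, cell_amplitude=25.0)
        cells, vesicles, profiles = radial_pipeline(
            cell_img, ves_img, ball_radius=60, intensity_window=(1.0, 20.0))
        ok = cells[~cells.discarded & (cells.n_children > 0)]
        assert len(ok) == 1
        assert ok.iloc[0].mean_distance == pytest.approx(30.0, rel=0.05)
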