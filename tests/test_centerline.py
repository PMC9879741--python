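"""Segmentation, bounding boxes, and centerline measurement against the
phantom's analytic ground truth."""

import dataclasses

import numpy as np
import pytest

from ctcenterline.centerline import (CenterlineConfig, bbox_and_centerline,
                                     detect_truncation, measure_centerlines,
                                     segment_body, segment_lungs)
from ctcenterline.core import Grid3D, Volume3D
from ctcenterline.phantom import (PhantomSpec, analytic_centerlines,
                                  region_masks, render_volume,
                                  sample_population)


@pytest.fixture(scope="module")
def plain_spec():
    """Body only: no lungs, couch pushed out of the field of view."""
    return PhantomSpec.from_diameters(243.0, 301.0, table_height_offset=-12.0,
                                      with_lungs=False, table_gap=1e6)


class TestSegmentBody:
    def test_mask_iou_vs_analytic_ellipsoid(self, plain_spec, grid):
        vol = render_volume(plain_spec, grid)
        mask = segment_body(vol)
        truth = region_masks(plain_spec, grid)["body"]
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_table_voxels_excluded(self, standard_spec, grid):
        vol = render_volume(standard_spec, grid)
        mask = segment_body(vol)
        table = region_masks(standard_spec, grid)["table"]
        assert not (mask & table).any()

    def test_blanket_does_not_move_centerline(self, standard_spec, grid):
        bare = measure_centerlines(render_volume(standard_spec, grid))
        wrapped = measure_centerlines(render_volume(
            dataclasses.replace(standard_spec, blanket_present=True), grid))
        assert abs(wrapped.body_centerline
                   - bare.body_centerline) < max(grid.spacing)

    def test_empty_volume_rejected(self, grid):
        vol = Volume3D(voxels=np.zeros(grid.shape, dtype=np.float32),
                       grid=grid)
        with pytest.raises(ValueError, match="no body"):
            segment_body(vol)

    def test_lungs_filled_into_body_mask(self, standard_spec, grid):
        vol = render_volume(standard_spec, grid)
        mask = segment_body(vol)
        lungs = region_masks(standard_spec, grid)["lungs"]
        assert (mask & lungs).sum() / lungs.sum() > 0.95


class TestSegmentLungs:
    def test_two_components_at_spec_centers(self, standard_spec, grid):
        vol = render_volume(standard_spec, grid)
        body = segment_body(vol)
        lungs, fallback = segment_lungs(vol, body)
        assert not fallback
        from scipy import ndimage
        labels, n = ndimage.label(lungs, structure=np.ones((3, 3, 3)))
        assert n == 2
        yc = standard_spec.table_height_offset
        centers = sorted(
            ndimage.center_of_mass(lungs, labels, range(1, n + 1)),
            key=lambda c: c[1])
        for com, off in zip(centers,
                            sorted(standard_spec.lung_center_offsets,
                                   key=lambda o: o[1])):
            y_mm = grid.coords(0)[0] + com[0] * grid.spacing[0]
            x_mm = grid.coords(1)[0] + com[1] * grid.spacing[1]
            assert abs(y_mm - (yc + off[0])) <= grid.spacing[0]
            assert abs(x_mm - off[1]) <= grid.spacing[1]

    def test_lungless_phantom_flagged(self, plain_spec, grid):
        vol = render_volume(plain_spec, grid)
        body = segment_body(vol)
        lungs, fallback = segment_lungs(vol, body)
        assert fallback

    def test_mirror_symmetry(self, standard_spec, grid):
        vol = render_volume(standard_spec, grid)
        mirrored = Volume3D(voxels=vol.voxels[:, ::-1, :].copy(),
                            grid=grid)
        a = measure_centerlines(vol)
        b = measure_centerlines(mirrored)
        assert b.lung_centerline == pytest.approx(a.lung_centerline)


class TestBBox:
    def test_single_voxel_degenerate_box(self, grid):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[10, 20, 5] = True
        box, cl = bbox_and_centerline(mask, grid)
        assert cl == pytest.approx(grid.coords(0)[10])
        assert box.anterior_limit == box.posterior_limit + 0  # degenerate
        # degenerate in the lateral/z directions as well
        assert box.lateral_limits[0] == box.lateral_limits[1]

    def test_empty_mask_rejected(self, grid):
        with pytest.raises(ValueError, match="empty"):
            bbox_and_centerline(np.zeros(grid.shape, dtype=bool), grid)

    def test_offset_recovered_within_half_voxel(self, standard_spec, grid):
        rep = measure_centerlines(render_volume(standard_spec, grid))
        assert abs(rep.body_centerline - (-12.0)) <= max(grid.spacing) / 2

    def test_scan_range_restriction_matches_analytic(self, grid):
        spec = PhantomSpec.from_diameters(243.0, 301.0,
                                          table_height_offset=-18.0)
        scan_range = (20.0, 180.0)
        vol = render_volume(spec, grid)
        rep = measure_centerlines(vol, scan_range=scan_range)
        gt = analytic_centerlines(spec, scan_range=scan_range)
        assert abs(rep.body_centerline
                   - gt.body_centerline) <= max(grid.spacing) / 2
        assert abs(rep.lung_centerline
                   - gt.lung_centerline) <= max(grid.spacing) / 2


class TestInvariances:
    def test_intensity_rescale_invariance(self, standard_spec, grid):
        vol = render_volume(standard_spec, grid)
        scaled = Volume3D(voxels=vol.voxels * 0.37, grid=grid)
        a = measure_centerlines(vol)
        b = measure_centerlines(scaled)
        assert b.body_centerline == pytest.approx(a.body_centerline)
        assert b.lung_centerline == pytest.approx(a.lung_centerline)

    def test_translation_equivariance(self, grid):
        base = PhantomSpec.from_diameters(243.0, 301.0,
                                          table_height_offset=-20.0)
        h = 24.0
        shifted = dataclasses.replace(base, table_height_offset=-20.0 + h)
        a = measure_centerlines(render_volume(base, grid))
        b = measure_centerlines(render_volume(shifted, grid))
        assert abs((b.body_centerline - a.body_centerline)
                   - h) <= max(grid.spacing) / 2


def test_per_slice_centerlines_track_offset(standard_spec, grid):
    """Per-slice body centerlines (the scan-range dependence view) sit at
    the programmed couch offset wherever the body is present."""
    vol = render_volume(standard_spec, grid)
    rep = measure_centerlines(vol, per_slice=True)
    vals = rep.per_slice_centerlines
    assert vals is not None and vals.shape[0] == grid.shape[2]
    present = ~np.isnan(vals)
    assert present.any()
    assert np.all(np.abs(vals[present] - (-12.0)) <= max(grid.spacing) / 2)


class TestTruncation:
    def test_contained_phantom_not_flagged(self, standard_spec, grid):
        vol = render_volume(standard_spec, grid)
        assert not detect_truncation(segment_body(vol), grid)

    def test_oversized_phantom_flagged(self):
        # vertical FOV 128 mm cannot hold a 243 mm AP body
        small = Grid3D.centered((32, 32, 16), (4.0, 10.0, 12.0))
        spec = PhantomSpec.from_diameters(243.0, 301.0, with_lungs=False,
                                          table_gap=1e6)
        vol = render_volume(spec, small)
        mask = segment_body(vol)
        assert detect_truncation(mask, small)

    def test_zero_fraction_flags_any_touch(self, grid):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[40:60, 40:60, :] = True
        mask[50, 0, 10] = True  # single lateral-boundary touch
        assert detect_truncation(mask, grid, slice_fraction=0.0)
        assert not detect_truncation(mask, grid, slice_fraction=0.5)


def test_oracle_closure_over_random_phantoms(grid):
    """Measured centerlines agree with the analytic oracle to half the
    largest voxel spacing for body and lungs (30-phantom spot check; the
    acceptance suite runs the full 100)."""
    tol = max(grid.spacing) / 2
    checked = 0
    for spec in sample_population(40, seed=3):
        try:
            vol = render_volume(spec, grid)
        except ValueError:
            continue
        rep = measure_centerlines(vol)
        if rep.truncated:
            continue
        gt = analytic_centerlines(spec, isocenter_y=grid.isocenter_y)
        assert abs(rep.body_centerline - gt.body_centerline) <= tol
        assert abs(rep.lung_centerline - gt.lung_centerline) <= tol
        checked += 1
        if checked >= 30:
            break
    assert checked >= 25
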