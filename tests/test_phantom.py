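"""Phantom generator: population sampling, rendering, projection, and the
analytic centerline oracle."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from ctcenterline.core import Grid3D
from ctcenterline.phantom import (DEFAULT_MISCENTER_SD, Demographics,
                                  PhantomSpec, ProjectionGeometry,
                                  analytic_centerlines,
                                  miscenter_sd_for_prevalence,
                                  project_localizer, region_masks,
                                  render_volume, sample_population,
                                  simulate_case)


class TestSamplePopulation:
    def test_seeded_reproducibility(self):
        a = sample_population(3, seed=7)
        b = sample_population(3, seed=7)
        assert a == b

    def test_diameter_means_match_demographics(self):
        specs = sample_population(5000, seed=11)
        d_ap = np.array([2 * s.body_semi_axis_ap for s in specs])
        d_lat = np.array([2 * s.body_semi_axis_lat for s in specs])
        # truncation at +-3 SD changes the mean negligibly vs 3 SE
        assert abs(d_ap.mean() - 243.0) < 3 * 36.0 / np.sqrt(5000)
        assert abs(d_lat.mean() - 301.0) < 3 * 53.0 / np.sqrt(5000)

    def test_miscenter_prevalence_matches_cohort(self):
        """Default SD solves P(|offset| > 10 mm) = 0.60 for a zero-mean
        normal; the sampled prevalence must agree."""
        sd = miscenter_sd_for_prevalence(10.0, 0.6)
        assert sd == pytest.approx(10.0 / stats.norm.ppf(0.7))
        assert DEFAULT_MISCENTER_SD == pytest.approx(sd)
        specs = sample_population(5000, seed=2)
        offs = np.array([s.table_height_offset for s in specs])
        assert abs(np.mean(np.abs(offs) > 10.0) - 0.60) < 0.02

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_population(0, seed=1)
        with pytest.raises(ValueError):
            sample_population(2, miscenter_sd=-1.0, seed=1)
        # a population whose truncation window is entirely non-positive
        bad = Demographics(d_ap_cm=(-100.0, 0.1), d_lat_cm=(30.0, 5.0))
        with pytest.raises(ValueError, match="non-physical"):
            sample_population(5, demographics=bad, seed=1)


class TestRenderVolume:
    def test_ellipsoid_volume_matches_analytic(self, grid):
        spec = PhantomSpec(body_semi_axis_ap=100.0, body_semi_axis_lat=140.0,
                           body_length=180.0, table_gap=1e6)  # no lungs/table
        vol = render_volume(spec, grid)
        voxel_volume = np.prod(grid.spacing)
        measured = float((vol.voxels / spec.intensity_levels.soft_tissue).sum()
                         * voxel_volume)
        analytic = 4.0 / 3.0 * np.pi * 100.0 * 140.0 * 90.0
        assert abs(measured / analytic - 1.0) < 0.01

    def test_centered_phantom_centroid_at_isocenter(self, grid):
        spec = PhantomSpec.from_diameters(243.0, 301.0, table_height_offset=0.0,
                                          with_lungs=False)
        spec = dataclasses.replace(spec, table_gap=1e6)
        vol = render_volume(spec, grid)
        w = vol.voxels.sum(axis=(1, 2))
        centroid = float((grid.coords(0) * w).sum() / w.sum())
        assert abs(centroid - grid.isocenter_y) < grid.spacing[0] / 2

    def test_discretization_convergence(self, standard_spec):
        coarse = Grid3D.centered((48, 48, 16), (8.0, 10.0, 12.0))
        fine = Grid3D.centered((96, 96, 32), (4.0, 5.0, 6.0))

        def centroid(grid):
            vol = render_volume(standard_spec, grid)
            mask = vol.voxels > 0.5
            w = mask.sum(axis=(1, 2)).astype(float)
            return float((grid.coords(0) * w).sum() / w.sum())

        assert abs(centroid(coarse) - centroid(fine)) < coarse.spacing[0] / 2

    def test_body_outside_grid_raises(self, standard_spec):
        tiny = Grid3D(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0),
                      origin=(2000.0, 2000.0, 2000.0))
        with pytest.raises(ValueError, match="outside"):
            render_volume(standard_spec, tiny)

    def test_rendering_deterministic(self, standard_spec, grid):
        a = render_volume(standard_spec, grid)
        b = render_volume(standard_spec, grid)
        assert np.array_equal(a.voxels, b.voxels)

    def test_lungs_inside_body(self, grid):
        for seed in (0, 1, 2):
            spec = sample_population(1, seed=seed)[0]
            spec = dataclasses.replace(spec, table_height_offset=0.0)
            masks = region_masks(spec, grid)
            assert masks["lungs"].sum() > 0
            assert not (masks["lungs"] & ~masks["body"]).any()


class TestProjectLocalizer:
    def _width_at_level(self, loc, level_fraction):
        """Sub-pixel lateral width of the equator-row profile at a given
        fraction of its maximum (linear interpolation of the crossings)."""
        prof = loc.pixels[loc.pixels.shape[0] // 2].astype(float)
        level = prof.max() * level_fraction
        x = loc.coords(1)
        above = np.nonzero(prof >= level)[0]
        i0, i1 = above[0], above[-1]
        # interpolate the crossing on both flanks
        left = x[i0]
        if i0 > 0 and prof[i0] != prof[i0 - 1]:
            t = (level - prof[i0 - 1]) / (prof[i0] - prof[i0 - 1])
            left = x[i0 - 1] + t * (x[i0] - x[i0 - 1])
        right = x[i1]
        if i1 < len(x) - 1 and prof[i1] != prof[i1 + 1]:
            t = (level - prof[i1 + 1]) / (prof[i1] - prof[i1 + 1])
            right = x[i1 + 1] + t * (x[i1] - x[i1 + 1])
        return right - left

    def test_parallel_body_width(self, grid):
        """The equator-row profile of an ellipsoid is an elliptical chord
        profile: its support spans the full lateral diameter, and its
        half-maximum width is sqrt(3)/2 of it."""
        spec = PhantomSpec.from_diameters(240.0, 300.0, with_lungs=False,
                                          table_gap=1e6)
        loc = project_localizer(render_volume(spec, grid))
        support = self._width_at_level(loc, 0.02)
        assert abs(support - 300.0) <= 2 * grid.spacing[1]
        half_max = self._width_at_level(loc, 0.5)
        assert abs(half_max - np.sqrt(3) / 2 * 300.0) <= grid.spacing[1]

    def test_divergent_at_zero_height_equals_parallel(self, standard_case,
                                                      grid):
        vol = standard_case.volume
        par = project_localizer(vol)
        div = project_localizer(vol, ProjectionGeometry(
            mode="divergent", sdd=600.0, body_center_height=0.0))
        assert np.array_equal(par.pixels, div.pixels)

    def test_divergent_magnifies_by_m(self, grid):
        spec = PhantomSpec.from_diameters(240.0, 300.0, with_lungs=False,
                                          table_gap=1e6)
        vol = render_volume(spec, grid)
        par = project_localizer(vol)
        h = 40.0
        m = 600.0 / (600.0 - h)
        div = project_localizer(vol, ProjectionGeometry(
            mode="divergent", sdd=600.0, body_center_height=h))
        w_par = self._width_at_level(par, 0.5)
        w_div = self._width_at_level(div, 0.5)
        assert w_div > w_par
        assert abs(w_div / w_par - m) < 0.02

    def test_body_at_source_plane_rejected(self, standard_case):
        geom = ProjectionGeometry(mode="divergent", sdd=600.0,
                                  body_center_height=600.0)
        with pytest.raises(ValueError, match="source"):
            project_localizer(standard_case.volume, geom)

    def test_projection_lateral_bbox_consistent_with_volume(self, grid):
        """Lateral extent of the parallel shadow matches the volume's body
        extent within one pixel."""
        spec = PhantomSpec.from_diameters(243.0, 301.0, with_lungs=False,
                                          table_gap=1e6)
        vol = render_volume(spec, grid)
        loc = project_localizer(vol)
        vol_cols = np.nonzero(vol.voxels.max(axis=(0, 2)) > 0.1)[0]
        loc_cols = np.nonzero(loc.pixels.max(axis=0) > 0.1 * loc.pixels.max())[0]
        assert abs(vol_cols[0] - loc_cols[0]) <= 1
        assert abs(vol_cols[-1] - loc_cols[-1]) <= 1


class TestAnalyticCenterlines:
    def test_offset_sets_body_centerline(self):
        spec = PhantomSpec.from_diameters(243.0, 301.0,
                                          table_height_offset=-12.0)
        gt = analytic_centerlines(spec, isocenter_y=0.0)
        assert gt.body_centerline == pytest.approx(-12.0)

    def test_lung_offset_relative_to_body(self):
        spec = PhantomSpec.from_diameters(243.0, 301.0)
        semi = spec.lung_semi_axes[0]
        offsets = tuple(
            (10.0, off[1], off[2]) for off in spec.lung_center_offsets)
        spec = dataclasses.replace(spec, lung_center_offsets=offsets)
        gt = analytic_centerlines(spec)
        assert gt.lung_centerline - gt.body_centerline == pytest.approx(10.0)

    def test_disjoint_scan_range_rejected(self, standard_spec):
        with pytest.raises(ValueError, match="disjoint"):
            analytic_centerlines(standard_spec, scan_range=(5000.0, 6000.0))

    def test_scan_range_matches_voxel_bbox_oracle(self, grid):
        """Restricting to the superior half must agree with a brute-force
        bounding box over the crisp voxel mask."""
        spec = PhantomSpec.from_diameters(243.0, 301.0,
                                          table_height_offset=-20.0)
        scan_range = (10.0, 200.0)
        gt = analytic_centerlines(spec, scan_range=scan_range)
        masks = region_masks(spec, grid)
        z = grid.coords(2)
        sel = (z >= scan_range[0]) & (z <= scan_range[1])
        body = masks["body"][:, :, sel]
        rows = np.nonzero(body.any(axis=(1, 2)))[0]
        y = grid.coords(0)
        voxel_cl = 0.5 * (y[rows.max()] + y[rows.min()])
        assert abs(voxel_cl - gt.body_centerline) <= grid.spacing[0] / 2


def test_simulated_localizer_carries_magnification(grid):
    """The divergent scout of a raised phantom is laterally wider than that
    of the same phantom at the isocenter — the physical cue that makes table
    height readable from a single localizer."""
    lo = dataclasses.replace(
        PhantomSpec.from_diameters(243.0, 301.0), table_height_offset=-30.0)
    hi = dataclasses.replace(lo, table_height_offset=30.0)
    case_lo = simulate_case(lo, grid)
    case_hi = simulate_case(hi, grid)
    w_lo = (case_lo.localizer.pixels.mean(axis=0) > 0.01).sum()
    w_hi = (case_hi.localizer.pixels.mean(axis=0) > 0.01).sum()
    assert w_hi > w_lo
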