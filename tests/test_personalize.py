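"""Template personalization, wall thickness and AHA-17 aggregation."""

import warnings

import numpy as np
import pytest

from lvshape.imaging import voxelize
from lvshape.mesh import LVMesh
from lvshape.personalize import (
    CoverageError,
    SegmentationTopologyError,
    aha17_map,
    aha_segment_of,
    fit_template,
    fitting_error,
    wall_thickness,
)
from lvshape.synthetic import LVGeometryParams, generate_lv_surface


def hemisphere_shell(r_endo=25.0, r_epi=35.0, n_circ=64, n_long=32) -> LVMesh:
    """Concentric hemispherical shells, pole down (synthetic phantom)."""
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    u = np.linspace(0.0, 1.0, n_long)
    phi = u * np.pi / 2
    grids = []
    for r in (r_endo, r_epi):
        pts = np.empty((n_long, n_circ, 3))
        pts[..., 0] = r * np.cos(phi)[:, None] * np.cos(theta)[None, :]
        pts[..., 1] = r * np.cos(phi)[:, None] * np.sin(theta)[None, :]
        pts[..., 2] = -r * np.sin(phi)[:, None]
        grids.append(pts)
    return LVMesh(endo_points=grids[0], epi_points=grids[1], node_theta=theta, node_u=u)


class TestWallThickness:
    def test_concentric_hemispheres_give_constant_gap(self):
        t = wall_thickness(hemisphere_shell())
        assert np.isfinite(t).all()
        assert np.abs(t - 10.0).max() < 0.1

    def test_constant_normal_offset_recovered(self, uniform_wall_mesh):
        t = wall_thickness(uniform_wall_mesh)
        valid = np.isfinite(t)
        assert valid.mean() > 0.99
        assert np.abs(t[valid] - 8.0).max() < 0.16  # 2% of 8 mm

    def test_septal_bump_peak_recovered(self, bump_mesh):
        t = wall_thickness(bump_mesh)
        assert np.nanmax(t) == pytest.approx(17.0, rel=0.02)


class TestAHA17:
    def test_uniform_phantom_has_all_segments_equal(self):
        mesh = hemisphere_shell()
        aha = aha17_map(mesh, wall_thickness(mesh))
        assert aha.seg_thickness_mm.shape == (17,)
        np.testing.assert_allclose(aha.seg_thickness_mm, 10.0, atol=0.1)

    def test_basal_anteroseptal_bump_elevates_only_segment_2(self):
        params = LVGeometryParams(
            base_thickness_mm=8.0,
            septal_bump_amp_mm=4.0,
            septal_bump_center=(0.0, 1.0 / 6.0),
            septal_bump_width=(np.pi / 6.0, 1.0 / 6.0),
            spiral_drift_rad=0.0,
            apical_dilation=0.0,
            lvot_inward_mm=0.0,
        )
        mesh = generate_lv_surface(params)
        aha = aha17_map(mesh, wall_thickness(mesh))
        elevation = aha.seg_thickness_mm - 8.0
        assert elevation[1] > 2.0  # segment 2 raised by more than half the bump
        others = np.delete(elevation, 1)
        assert others.max() < 2.0

    def test_segment_lookup_follows_bullseye_convention(self):
        assert aha_segment_of(0.1, 0.0) == 2  # basal anteroseptal at theta=0
        assert aha_segment_of(0.5, 0.0) == 8
        assert aha_segment_of(0.1, np.pi) == 5  # opposite wall: inferolateral
        assert aha_segment_of(0.8, 0.0) == 14
        assert aha_segment_of(1.0, 1.3, is_apex_row=True) == 17

    def test_insufficient_coverage_rejected(self, uniform_wall_mesh):
        t = wall_thickness(uniform_wall_mesh)
        t[: t.shape[0] // 2] = np.nan
        with pytest.raises(CoverageError):
            aha17_map(uniform_wall_mesh, t)


class TestFittingError:
    def test_contours_on_surface_have_zero_distance(self, uniform_wall_mesh):
        from lvshape.imaging import ContourStack, SliceContours

        # sample contour points exactly at mesh nodes of two interior rows
        slices = []
        for i in (4, 10):
            endo_ring = uniform_wall_mesh.endo_points[i]
            epi_ring = uniform_wall_mesh.epi_points[i]
            slices.append(
                SliceContours(
                    z=float(endo_ring[0, 2]), endo=[endo_ring], epi=[epi_ring]
                )
            )
        report = fitting_error(uniform_wall_mesh, ContourStack(slices=slices))
        assert report.mean_error_mm < 1e-9

    def test_normal_offset_contours_measure_the_offset(self, uniform_wall_mesh):
        from lvshape.imaging import ContourStack, SliceContours

        normals = uniform_wall_mesh.node_normals("endo")
        ring, n_ring = uniform_wall_mesh.endo_points[10], normals[10]
        displaced = ring + 2.0 * n_ring
        stack = ContourStack(
            slices=[SliceContours(z=float(ring[0, 2]), endo=[displaced], epi=[])]
        )
        report = fitting_error(uniform_wall_mesh, stack)
        assert report.mean_error_mm == pytest.approx(2.0, abs=0.05)

    def test_endo_contours_against_epi_surface_measure_wall_thickness(
        self, uniform_wall_mesh
    ):
        from lvshape.imaging import ContourStack, SliceContours

        ring = uniform_wall_mesh.endo_points[10]
        stack = ContourStack(
            slices=[SliceContours(z=float(ring[0, 2]), endo=[], epi=[ring])]
        )
        report = fitting_error(uniform_wall_mesh, stack)
        assert report.mean_error_mm == pytest.approx(8.0, rel=0.05)

    def test_empty_stack_rejected(self, uniform_wall_mesh):
        from lvshape.imaging import ContourStack

        with pytest.raises(ValueError):
            fitting_error(uniform_wall_mesh, ContourStack(slices=[]))


class TestFitTemplate:
    def test_fit_reaches_half_voxel_accuracy_on_cmr_spacing(self, bump_mesh, template):
        mask, _ = voxelize(bump_mesh, 2.0, 8.0)
        fitted, report = fit_template(mask, template)
        assert report.mean_error_mm <= 1.25
        assert fitted.topology_id == template.topology_id

    def test_translation_equivariance(self, bump_mesh, template):
        mask, _ = voxelize(bump_mesh, 2.0, 8.0)
        shifted_mesh = bump_mesh.with_points(bump_mesh.as_points() + [10.0, 0.0, 0.0])
        mask_shifted, _ = voxelize(shifted_mesh, 2.0, 8.0)
        fit_a, rep_a = fit_template(mask, template)
        fit_b, rep_b = fit_template(mask_shifted, template)
        shift = fit_b.as_points().mean(axis=0) - fit_a.as_points().mean(axis=0)
        np.testing.assert_allclose(shift, [10.0, 0.0, 0.0], atol=1.0)
        assert rep_b.mean_error_mm == pytest.approx(rep_a.mean_error_mm, abs=0.15)

    def test_round_trip_recovers_node_positions(self, bump_mesh, template):
        """Voxelize at 1 mm isotropic, refit: nodes within a voxel diagonal."""
        mask, _ = voxelize(bump_mesh, 1.0, 1.0)
        fitted, _ = fit_template(mask, template)
        err = np.linalg.norm(fitted.as_points() - bump_mesh.as_points(), axis=1)
        assert err.mean() < np.sqrt(3.0)

    def test_error_decreases_with_finer_spacing(self, bump_mesh, template):
        errors = []
        for spacing in ((2.5, 10.0), (2.0, 8.0), (1.0, 4.0)):
            mask, _ = voxelize(bump_mesh, *spacing)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, report = fit_template(mask, template)
            errors.append(report.mean_error_mm)
        assert errors[2] <= errors[0] + 1e-9

    def test_cavityless_mask_rejected(self, template, bump_mesh):
        mask, _ = voxelize(bump_mesh, 2.0, 8.0)
        solid = mask
        solid.data = np.ones_like(mask.data)
        solid.data[0] = solid.data[-1] = False
        solid.data[:, 0] = solid.data[:, -1] = False
        with pytest.raises(SegmentationTopologyError):
            fit_template(solid, template)

    def test_fitted_cohort_thickness_tracks_generator_wall(self, small_cohort, template):
        """Mean fitted thickness correlates with the generative baseline wall."""
        t0s, fitted_means = [], []
        for s in small_cohort[::3]:
            mask, _ = voxelize(s.mesh, 2.0, 8.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted, _ = fit_template(mask, template)
            t = wall_thickness(fitted)
            fitted_means.append(np.nanmean(t))
            t0s.append(s.params.base_thickness_mm)
        r = np.corrcoef(t0s, fitted_means)[0, 1]
        assert r > 0.95
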