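"""Signed surface differences and plateau agreement metrics."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from meniscus3d import (
    MeasurementParams,
    TibialFrame,
    cohort_summary,
    cut_medial_plateau,
    make_thickened_section,
    plateau_metrics,
    signed_surface_difference,
)
from meniscus3d.surface_compare import ComparisonError, SurfaceComparison
from meniscus3d._geometry import signed_volume


def _identity_frame(origin=(0.0, 0.0, 0.0)):
    return TibialFrame(
        origin=np.asarray(origin, dtype=float),
        axis_x=np.array([1.0, 0.0, 0.0]),
        axis_y=np.array([0.0, 1.0, 0.0]),
        axis_z=np.array([0.0, 0.0, 1.0]),
    )


def _sphere_plateau(radius, subdivisions=4):
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return cut_medial_plateau(sphere, _identity_frame(), MeasurementParams())


@pytest.fixture(scope="module")
def plateau_r20():
    return _sphere_plateau(20.0)


@pytest.fixture(scope="module")
def plateau_r203():
    return _sphere_plateau(20.3)


class TestSignedSurfaceDifference:
    def test_model_vs_itself_is_zero(self, plateau_r20):
        comp = signed_surface_difference(plateau_r20, plateau_r20, n_points=2000)
        assert abs(comp.mean) < 1e-9
        assert comp.max_abs < 1e-9

    def test_concentric_spheres_signed_offset(self, plateau_r20, plateau_r203):
        comp = signed_surface_difference(plateau_r20, plateau_r203, n_points=4000)
        assert comp.mean == pytest.approx(0.3, abs=0.01)
        assert comp.ci95_low <= comp.mean <= comp.ci95_high

    def test_antisymmetry(self, plateau_r20, plateau_r203):
        fwd = signed_surface_difference(plateau_r20, plateau_r203, n_points=4000)
        rev = signed_surface_difference(plateau_r203, plateau_r20, n_points=4000)
        assert fwd.mean == pytest.approx(-rev.mean, abs=0.02)

    def test_sampling_stability(self, plateau_r20, plateau_r203):
        a = signed_surface_difference(plateau_r20, plateau_r203, n_points=4000)
        b = signed_surface_difference(plateau_r20, plateau_r203, n_points=8000)
        assert abs(a.mean - b.mean) < 0.02

    def test_cut_face_exclusion_regression(self):
        # same sphere cut at different depths: articular surfaces coincide,
        # caps differ; excluding cut faces must keep the mean at zero
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
        a = cut_medial_plateau(sphere, _identity_frame(), MeasurementParams(cut_depth=10.0))
        b = cut_medial_plateau(sphere, _identity_frame(), MeasurementParams(cut_depth=12.0))
        excl = signed_surface_difference(a, b, n_points=4000, exclude_cut_faces=True)
        assert abs(excl.mean) < 1e-6
        incl = signed_surface_difference(a, b, n_points=4000, exclude_cut_faces=False)
        assert incl.max_abs > excl.max_abs

    def test_disjoint_models_rejected(self, plateau_r20):
        far = _sphere_plateau(20.0)
        far.mesh.apply_translation([500.0, 0.0, 0.0])
        with pytest.raises(ComparisonError):
            signed_surface_difference(plateau_r20, far)

    def test_emulated_pair_bounded(self, phantom_default, emulated_tibia_pair):
        ct, mri = emulated_tibia_pair
        from meniscus3d import fit_tibial_frame, icp_register, transfer_frame

        spec = phantom_default.spec
        frame_ct = fit_tibial_frame(ct, notch_plane_point=[0, spec.notch_level_y, 0])
        xf = icp_register(ct, mri, n_samples=3000, tol=1e-3)
        frame_mri = transfer_frame(frame_ct, xf)
        pa = cut_medial_plateau(ct, frame_ct)
        pb = cut_medial_plateau(mri, frame_mri)
        comp = signed_surface_difference(pa, pb, n_points=4000)
        assert abs(comp.mean) <= 0.6


class TestPlateauMetrics:
    def test_cuboid_values(self):
        tibia = trimesh.creation.box(extents=[60, 200, 80])
        tibia.apply_translation([0, -100, 0])
        plat = cut_medial_plateau(tibia, _identity_frame(), MeasurementParams())
        sec = make_thickened_section(plat)
        met = plateau_metrics(plat, sec)
        assert met.volume == pytest.approx(60 * 10 * 40, rel=1e-9)
        assert met.cross_sectional_area == pytest.approx(60 * 40, rel=1e-9)

    def test_rigid_invariance(self, phantom_default):
        from meniscus3d import RigidTransform, fit_tibial_frame

        sec0 = phantom_default.section
        met0 = plateau_metrics(phantom_default.plateau, sec0)
        R = Rotation.from_euler("xyz", [8, -5, 12], degrees=True).as_matrix()
        x = RigidTransform(R, np.array([4.0, 2.0, -6.0]))
        tibia2 = x.apply_mesh(phantom_default.tibia)
        spec = phantom_default.spec
        notch2 = x.apply(np.array([[0.0, spec.notch_level_y, 0.0]]))[0]
        frame2 = fit_tibial_frame(
            tibia2,
            notch_plane_point=notch2,
            notch_plane_normal=R @ np.array([0.0, 1.0, 0.0]),
            medial_hint_world=R @ np.array([0.0, 0.0, 1.0]),
        )
        plat2 = cut_medial_plateau(tibia2, frame2)
        sec2 = make_thickened_section(plat2)
        met2 = plateau_metrics(plat2, sec2)
        assert met2.volume == pytest.approx(met0.volume, rel=1e-3)
        assert met2.cross_sectional_area == pytest.approx(
            met0.cross_sectional_area, rel=1e-3
        )


class TestCohortSummary:
    def _comp(self, mean, label=""):
        return SurfaceComparison(
            per_point_distances=np.array([mean]),
            mean=mean,
            ci95_low=mean - 0.3,
            ci95_high=mean + 0.3,
            max_abs=abs(mean),
            n_points=1,
            excluded_cut_faces=True,
            label=label,
        )

    def test_single_comparison(self):
        s = cohort_summary([self._comp(0.1)])
        assert s.minimal.mean == s.maximal.mean == 0.1

    def test_min_max_selection(self):
        # the min/max subject pattern of a published ten-knee cohort
        s = cohort_summary([self._comp(m) for m in (-0.15, 0.00, 0.24)])
        assert s.minimal.mean == pytest.approx(-0.15)
        assert s.maximal.mean == pytest.approx(0.24)
        assert list(s.table.columns)[:2] == ["participant", "mean_mm"]

    def test_ties_first_occurrence(self):
        comps = [self._comp(0.1, "a"), self._comp(0.1, "b")]
        s = cohort_summary(comps)
        assert s.minimal.label == "a"
        assert s.maximal.label == "a"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])
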