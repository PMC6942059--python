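"""Tangent-rectangle frame fitting, ICP registration, frame transfer."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from meniscus3d import (
    PhantomSpec,
    MeniscusSpec,
    OsteophyteSpec,
    RigidTransform,
    extract_section,
    fit_tangent_rectangle,
    fit_tibial_frame,
    icp_register,
    make_phantom,
    transfer_frame,
)
from meniscus3d.tibial_frame import (
    EmptySectionError,
    PlanarSection,
    RectangleFitError,
    build_frame,
)


def _two_circle_section(rot_deg=0.0):
    th = np.linspace(0, 2 * np.pi, 2001)[:-1]
    c1 = np.column_stack([20 * np.cos(th), 25 + 20 * np.sin(th)])
    c2 = np.column_stack([20 * np.cos(th), -25 + 20 * np.sin(th)])
    a = np.deg2rad(rot_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return PlanarSection(
        plane_point=np.zeros(3),
        plane_normal=np.array([0.0, 1.0, 0.0]),
        basis_u=np.array([1.0, 0.0, 0.0]),
        basis_v=np.array([0.0, 0.0, 1.0]),
        contours=[c1 @ R.T, c2 @ R.T],
    ), R


class TestTangentRectangle:
    def test_two_circles_closed_form(self):
        sec, _ = _two_circle_section()
        rect = fit_tangent_rectangle(sec, [0.0, 1.0])
        assert np.allclose(rect.center, [0, 0, 0], atol=1e-3)
        assert rect.half_extent_x == pytest.approx(20.0, abs=1e-3)
        assert rect.half_extent_z == pytest.approx(45.0, abs=1e-3)
        assert np.allclose(rect.edge_dir_z, [0, 0, 1], atol=1e-3)

    def test_in_plane_rotation_equivariance(self):
        sec, R = _two_circle_section(rot_deg=17.0)
        rect = fit_tangent_rectangle(sec, R @ np.array([0.0, 1.0]))
        zd = np.array([rect.edge_dir_z[0], rect.edge_dir_z[2]])
        assert np.allclose(zd, R @ np.array([0.0, 1.0]), atol=1e-3)
        c2 = np.array([rect.center[0], rect.center[2]])
        assert np.allclose(c2, [0.0, 0.0], atol=1e-3)

    def test_tangency_no_point_outside(self):
        sec, _ = _two_circle_section()
        rect = fit_tangent_rectangle(sec, [0.0, 1.0])
        pts = np.vstack(sec.contours)
        xd = np.array([rect.edge_dir_x[0], rect.edge_dir_x[2]])
        zd = np.array([rect.edge_dir_z[0], rect.edge_dir_z[2]])
        c2 = np.array([rect.center[0], rect.center[2]])
        rel_x = (pts - c2) @ xd
        rel_z = (pts - c2) @ zd
        assert rel_x.min() >= -rect.half_extent_x - 1e-6
        assert rel_z.max() <= rect.half_extent_z + 1e-6
        assert rel_z.min() >= -rect.half_extent_z - 1e-6

    def test_rectangle_unchanged_by_osteophyte_above_notch(self):
        clean = PhantomSpec()
        bumpy = PhantomSpec(osteophyte=OsteophyteSpec(radial_mm=3.0))
        tib_a, _, _ = make_phantom(clean)
        tib_b, _, _ = make_phantom(bumpy)
        notch = [0.0, clean.notch_level_y, 0.0]
        ra = fit_tangent_rectangle(extract_section(tib_a, notch, [0, 1, 0]), [0, 1])
        rb = fit_tangent_rectangle(extract_section(tib_b, notch, [0, 1, 0]), [0, 1])
        assert np.allclose(ra.center, rb.center, atol=1e-6)
        assert np.allclose(ra.edge_dir_z, rb.edge_dir_z, atol=1e-9)

    def test_tiny_contour_raises(self):
        sec = PlanarSection(
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 1.0, 0.0]),
            basis_u=np.array([1.0, 0.0, 0.0]),
            basis_v=np.array([0.0, 0.0, 1.0]),
            contours=[np.array([[0.0, 0.0], [1.0, 0.0]])],
        )
        with pytest.raises(RectangleFitError):
            fit_tangent_rectangle(sec, [0, 0])


class TestSectionExtraction:
    def test_sphere_circle(self, sphere20):
        sec = extract_section(sphere20, [0, 0.37, 0], [0, 1, 0])
        assert len(sec.contours) == 1
        ring = sec.contours[0]
        x, z = ring[:, 0], ring[:, 1]
        area = 0.5 * (np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1)))
        assert area == pytest.approx(np.pi * (20**2 - 0.37**2), rel=0.01)

    def test_missing_plane_raises(self, sphere20):
        with pytest.raises(EmptySectionError):
            extract_section(sphere20, [0, 50.0, 0], [0, 1, 0])

    def test_phantom_notch_topology(self, phantom_default):
        sec = extract_section(
            phantom_default.tibia,
            [0.0, phantom_default.spec.notch_level_y, 0.0],
            [0, 1, 0],
        )
        assert len(sec.contours) == phantom_default.truth.notch_contours


class TestBuildFrame:
    def test_explicit_offset_translates_origin(self, phantom_default):
        spec = phantom_default.spec
        sec = extract_section(
            phantom_default.tibia, [0.0, spec.notch_level_y, 0.0], [0, 1, 0]
        )
        rect = fit_tangent_rectangle(sec, [0, 1])
        frame = build_frame(rect, phantom_default.tibia, superior_offset=15.0)
        assert frame.origin[1] == pytest.approx(spec.notch_level_y + 15.0, abs=1e-9)

    def test_offset_outside_mesh_raises(self, phantom_default):
        from meniscus3d.tibial_frame import FrameError

        spec = phantom_default.spec
        sec = extract_section(
            phantom_default.tibia, [0.0, spec.notch_level_y, 0.0], [0, 1, 0]
        )
        rect = fit_tangent_rectangle(sec, [0, 1])
        with pytest.raises(FrameError):
            build_frame(rect, phantom_default.tibia, superior_offset=100.0)

    def test_axes_orthonormal_right_handed(self, phantom_default):
        f = phantom_default.frame
        assert abs(np.linalg.norm(f.axis_x) - 1) < 1e-12
        assert abs(f.axis_x @ f.axis_z) < 1e-9
        assert np.allclose(f.axis_y, np.cross(f.axis_z, f.axis_x), atol=1e-9)

    def test_recovers_construction_frame(self, phantom_default):
        truth = phantom_default.truth.frame
        frame = phantom_default.frame
        assert np.linalg.norm(frame.origin - truth.origin) < 0.5
        for ax in ("axis_x", "axis_y", "axis_z"):
            cosang = np.clip(getattr(frame, ax) @ getattr(truth, ax), -1, 1)
            assert np.degrees(np.arccos(cosang)) < 1.0


class TestICP:
    def test_identity_on_same_mesh(self, phantom_default):
        xf, info = icp_register(
            phantom_default.tibia,
            phantom_default.tibia,
            max_iter=10,
            tol=1e-8,
            n_samples=3000,
            full_output=True,
        )
        assert info["rms"] < 1e-6
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-9)

    def test_rms_monotone_nonincreasing(self, emulated_tibia_pair):
        ct, mri = emulated_tibia_pair
        _, info = icp_register(ct, mri, n_samples=3000, tol=1e-4, full_output=True)
        trace = info["trace"]
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))

    def test_emulated_pair_residual_bounded(self, emulated_tibia_pair):
        ct, mri = emulated_tibia_pair
        _, info = icp_register(ct, mri, n_samples=3000, tol=1e-4, full_output=True)
        assert info["rms"] <= 0.5


class TestRigidTransform:
    def test_compose_inverse_identity(self, rng):
        R = Rotation.random(random_state=7).as_matrix()
        x = RigidTransform(R, rng.normal(size=3))
        ident = x.compose(x.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0, atol=1e-12)

    def test_transfer_frame_group_properties(self, phantom_default):
        frame = phantom_default.frame
        R = Rotation.from_euler("xyz", [4, 9, -3], degrees=True).as_matrix()
        x = RigidTransform(R, np.array([1.0, 2.0, 3.0]))
        back = transfer_frame(transfer_frame(frame, x), x.inverse())
        assert np.allclose(back.origin, frame.origin, atol=1e-9)
        assert np.allclose(back.axis_z, frame.axis_z, atol=1e-12)

    def test_pure_translation_moves_origin_only(self, phantom_default):
        frame = phantom_default.frame
        x = RigidTransform(np.eye(3), np.array([0.0, 5.0, 0.0]))
        out = transfer_frame(frame, x)
        assert np.allclose(out.origin, frame.origin + [0, 5, 0])
        assert np.allclose(out.axis_x, frame.axis_x)

    def test_json_round_trip(self, phantom_default):
        frame = phantom_default.frame
        from meniscus3d.tibial_frame import TibialFrame

        back = TibialFrame.from_json(frame.to_json())
        assert np.allclose(back.origin, frame.origin)
        assert back.side == frame.side
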