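"""Model construction, joint frames, marker kinematics, parameter packing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neckdyn import synth
from neckdyn.model import (
    State,
    build_specimen_model,
    compute_joint_frame,
    default_bushing_init,
    forward_kinematics_markers,
    free_coordinates,
    pack_parameters,
    state_to_poses,
    unpack_parameters,
)


@pytest.fixture(scope="module")
def geometry():
    geom, _, _, _ = synth.generate_specimen(0)
    return geom


class TestBuildSpecimenModel:
    def test_equal_mass_split(self, geometry):
        model = build_specimen_model(geometry, 0.390)
        assert [s.mass for s in model.segments] == pytest.approx([0.078] * 5)

    def test_identity_geometry_gives_axis_aligned_frames(self):
        geom, _, _, _ = synth.generate_specimen(0)
        geom.sagittal_tilts = np.zeros(4)
        model = build_specimen_model(geom, 0.4)
        for j in model.joints:
            np.testing.assert_allclose(j.orientation_in_caudal, np.eye(3),
                                       atol=1e-12)

    def test_tilted_joint_frame_angle(self, geometry):
        # the joint y-axis makes exactly the configured sagittal angle
        # with the global vertical
        model = build_specimen_model(geometry, 0.4)
        for j, tilt in zip(model.joints, geometry.sagittal_tilts):
            y_axis = j.orientation_in_caudal[:, 1]
            angle = np.arccos(np.clip(y_axis @ np.array([0, 1, 0]), -1, 1))
            assert angle == pytest.approx(tilt, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        {"mass_kg": -1.0},
        {"mass_kg": 0.0},
        {"mass_split": [0.5, 0.5, 0.0, 0.0, 0.1]},
        {"mass_split": [1.0, 0.0, 0.0]},
    ])
    def test_invalid_inputs_raise(self, geometry, bad):
        kwargs = {"mass_kg": 0.4, **bad}
        with pytest.raises(ValueError):
            build_specimen_model(geometry, **kwargs)

    def test_constraint_layout(self, geometry):
        model = build_specimen_model(geometry, 0.4)
        assert model.constraints.mobility == {
            "C2": "axial_translation_only", "C3": "free", "C4": "free",
            "C5": "free", "C6": "fixed"}

    def test_preload_total(self, geometry):
        model = build_specimen_model(geometry, 0.4)
        assert model.preload.total_N == pytest.approx(152.0)


class TestComputeJointFrame:
    def test_parallel_horizontal_planes(self):
        up = np.array([0.0, 1.0, 0.0])
        jf = compute_joint_frame((np.array([0, 0, 0.0]), up),
                                 (np.array([0, 0.002, 0.0]), up))
        np.testing.assert_allclose(jf.origin_in_caudal, [0, 0.001, 0],
                                   atol=1e-15)
        np.testing.assert_allclose(jf.orientation_in_caudal, np.eye(3),
                                   atol=1e-15)

    def test_tilted_caudal_plane_rotates_frame_about_z(self):
        a = np.deg2rad(10.0)
        n = np.array([-np.sin(a), np.cos(a), 0.0])
        jf = compute_joint_frame((np.zeros(3), n), (np.zeros(3), n))
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0],
                       [0, 0, 1.0]])
        np.testing.assert_allclose(jf.orientation_in_caudal, Rz, atol=1e-12)

    def test_coincident_plane_centres(self):
        up = np.array([0.0, 1.0, 0.0])
        p = np.array([0.01, 0.02, 0.03])
        jf = compute_joint_frame((p, up), (p, up))
        np.testing.assert_allclose(jf.origin_in_caudal, p)

    def test_zero_normal_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_joint_frame((np.zeros(3), np.zeros(3)),
                                (np.zeros(3), np.array([0, 1.0, 0])))

    def test_anterior_parallel_to_normal_raises(self):
        n = np.array([1.0, 0.0, 0.0])  # normal along the anterior reference
        with pytest.raises(ValueError, match="parallel"):
            compute_joint_frame((np.zeros(3), n), (np.zeros(3), n))

    def test_frames_are_orthonormal_right_handed(self, geometry):
        model = build_specimen_model(geometry, 0.4)
        for j in model.joints:
            R = j.orientation_in_caudal
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestForwardKinematics:
    def _model(self):
        geom, _, mass, _ = synth.generate_specimen(0)
        return build_specimen_model(geom, mass)

    def test_neutral_state_gives_rest_positions(self):
        model = self._model()
        n = len(free_coordinates(model))
        markers = forward_kinematics_markers(model, State(np.zeros(n), np.zeros(n)))
        for s in model.segments:
            for name, local in s.marker_points.items():
                np.testing.assert_allclose(markers[name],
                                           s.rest_position + local, atol=1e-15)

    def test_rigid_translation_shifts_cluster(self):
        model = self._model()
        coords = free_coordinates(model)
        q = np.zeros(len(coords))
        shift = np.array([0.0, -1e-3, 0.0])
        q[coords.index(("C4", "ty"))] = shift[1]
        moved = forward_kinematics_markers(model, State(q, np.zeros_like(q)))
        rest = forward_kinematics_markers(model, State(np.zeros_like(q),
                                                       np.zeros_like(q)))
        for name in moved:
            expected = shift if name.startswith("C4CL") else np.zeros(3)
            np.testing.assert_allclose(moved[name] - rest[name], expected,
                                       atol=1e-15)

    def test_rotation_about_z_maps_offsets(self):
        # a 90 degree rotation about the segment z-axis maps a local marker
        # offset (a, b, c) to (-b, a, c) about the segment origin
        model = self._model()
        coords = free_coordinates(model)
        q = np.zeros(len(coords))
        q[coords.index(("C3", "rz"))] = np.pi / 2
        markers = forward_kinematics_markers(model, State(q, np.zeros_like(q)))
        seg = model.segment("C3")
        for name, local in seg.marker_points.items():
            expected = seg.rest_position + np.array(
                [-local[1], local[0], local[2]])
            np.testing.assert_allclose(markers[name], expected, atol=1e-12)

    def test_state_size_mismatch_raises(self):
        model = self._model()
        with pytest.raises(ValueError, match="coordinates"):
            state_to_poses(model, State(np.zeros(3), np.zeros(3)))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rigid_body_preserves_intra_segment_distances(self, seed):
        model = self._model()
        rng = np.random.default_rng(seed)
        n = len(free_coordinates(model))
        q = rng.uniform(-0.01, 0.01, n)
        markers = forward_kinematics_markers(model, State(q, np.zeros(n)))
        for s in model.segments:
            names = list(s.marker_points)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    d_rest = np.linalg.norm(s.marker_points[names[i]]
                                            - s.marker_points[names[j]])
                    d_now = np.linalg.norm(markers[names[i]] - markers[names[j]])
                    assert d_now == pytest.approx(d_rest, abs=1e-12)


class TestParameterPacking:
    def test_round_trip_identity(self):
        bushings = [default_bushing_init() for _ in range(4)]
        for i, b in enumerate(bushings):
            b.k_trans[1] = 1e6 * (i + 1)
            b.b_trans[0] = 100.0 * (i + 1)
        p = pack_parameters(bushings)
        out = unpack_parameters(p, bushings)
        np.testing.assert_allclose(pack_parameters(out), p)
        for a, b in zip(out, bushings):
            np.testing.assert_allclose(a.k_trans, b.k_trans)
            np.testing.assert_allclose(a.b_rot, b.b_rot)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError, match="16"):
            unpack_parameters(np.ones(15), [default_bushing_init()] * 4)

    def test_negative_entries_raise(self):
        p = np.ones(16)
        p[3] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            unpack_parameters(p, [default_bushing_init()] * 4)

    def test_unpack_leaves_fixed_dof_untouched(self):
        template = [default_bushing_init() for _ in range(4)]
        out = unpack_parameters(np.full(16, 123.0), template)
        for t, o in zip(template, out):
            np.testing.assert_allclose(o.k_rot, t.k_rot)
            np.testing.assert_allclose(o.b_rot, t.b_rot)
            assert o.k_trans[2] == t.k_trans[2]  # lateral untouched

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pack_unpack_bijection(self, seed):
        rng = np.random.default_rng(seed)
        p = 10.0 ** rng.uniform(1, 8, 16)
        template = [default_bushing_init() for _ in range(4)]
        np.testing.assert_allclose(
            pack_parameters(unpack_parameters(p, template)), p)
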