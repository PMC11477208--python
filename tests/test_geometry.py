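"""Crossbridge frame construction, tail angles, and densities."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from myolever.geometry import (
    CrossbridgeFrame,
    angle_density,
    angle_timeseries,
    build_crossbridge_frame,
    compute_tail_angles,
    superpose_to_reference,
    tail_vector,
)
from myolever.model_io import Selection, Trajectory, select
from myolever.synthetic import apo_spec, make_hinged_system, simulate_trajectories

from conftest import make_model

IDENTITY_FRAME = CrossbridgeFrame(
    origin=np.zeros(3),
    e1=np.array([1.0, 0.0, 0.0]),
    e2=np.array([0.0, 1.0, 0.0]),
    e3=np.array([0.0, 0.0, 1.0]),
)


class TestBuildFrame:
    def _pseudo_actin(self, rng):
        """Helical pseudo-filament along z, plus an anchor blob at +x."""
        pts = []
        for su in range(5):
            z = (su - 2) * 27.0
            for m in range(8):
                th = 2 * np.pi * m / 8 + 0.6 * su
                pts.append([6 * np.cos(th), 6 * np.sin(th), z])
        actin = np.asarray(pts)
        anchor = rng.normal(size=(10, 3)) + np.array([40.0, 0.0, 0.0])
        coords = np.vstack([actin, anchor])
        chain = ["F"] * len(actin) + ["A"] * len(anchor)
        resid = list(range(1, len(actin) + 1)) + list(range(1, len(anchor) + 1))
        return make_model(coords, resid=resid, chain=chain)

    def test_axes_match_independent_principal_axis(self):
        rng = np.random.default_rng(0)
        model = self._pseudo_actin(rng)
        actin = select(model, "chain F")
        anchor = select(model, "chain A")
        frame = build_crossbridge_frame(model, actin, anchor)
        # independent principal axis: SVD of centered actin coordinates
        pts = model.coords[actin.indices]
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        principal = vt[0]
        assert abs(abs(frame.e2 @ principal) - 1.0) < 1e-9
        np.testing.assert_allclose(frame.origin, pts.mean(axis=0), atol=1e-12)
        assert frame.e2[2] > 0.99          # oriented first -> last atom (+z)
        assert frame.e1 @ np.array([1.0, 0, 0]) > 0.95  # toward the anchor

    def test_axes_orthonormal_right_handed(self):
        rng = np.random.default_rng(1)
        model = self._pseudo_actin(rng)
        frame = build_crossbridge_frame(model, select(model, "chain F"),
                                        select(model, "chain A"))
        basis = np.column_stack([frame.e1, frame.e2, frame.e3])
        np.testing.assert_allclose(basis.T @ basis, np.eye(3), atol=1e-9)
        assert np.linalg.det(basis) > 0

    def test_coincident_actin_atoms_rejected(self):
        coords = np.vstack([np.zeros((5, 3)), [[10.0, 0, 0]]])
        model = make_model(coords, chain=["F"] * 5 + ["A"],
                           resid=[1, 2, 3, 4, 5, 1])
        with pytest.raises(ValueError, match="degenerate"):
            build_crossbridge_frame(model, select(model, "chain F"),
                                    select(model, "chain A"))

    def test_anchor_on_filament_axis_rejected(self):
        pts = np.array([[0.0, 0, z] for z in (-10, -5, 0, 5, 10)])
        coords = np.vstack([pts, [[0.0, 0.0, 30.0]]])
        model = make_model(coords, chain=["F"] * 5 + ["A"],
                           resid=[1, 2, 3, 4, 5, 1])
        with pytest.raises(ValueError, match="e1 is undefined"):
            build_crossbridge_frame(model, select(model, "chain F"),
                                    select(model, "chain A"))


class TestSuperpose:
    def _traj_and_ref(self, rng, transform=None):
        base = rng.normal(size=(12, 3)) * 6
        top = make_model(base)
        frames = base[None].copy()
        if transform is not None:
            rot, tr = transform
            frames = (base @ rot.T + tr)[None]
        traj = Trajectory(topology=top, frames=frames, timestep=1.0)
        sel = Selection(np.arange(12))
        return traj, top, sel

    def test_identity_when_already_aligned(self):
        rng = np.random.default_rng(0)
        traj, ref, sel = self._traj_and_ref(rng)
        out = superpose_to_reference(traj, sel, ref, sel)
        np.testing.assert_allclose(out.frames[0], ref.coords, atol=1e-12)

    def test_removes_rigid_motion(self):
        rng = np.random.default_rng(1)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        traj, ref, sel = self._traj_and_ref(rng, transform=(rot, np.array([5.0, -3, 2])))
        out = superpose_to_reference(traj, sel, ref, sel)
        np.testing.assert_allclose(out.frames[0], ref.coords, atol=1e-9)

    def test_preserves_internal_geometry(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 3)) * 5
        top = make_model(base)
        frames = rng.normal(size=(3, 10, 3)) * 5
        traj = Trajectory(topology=top, frames=frames, timestep=1.0)
        sel = Selection(np.arange(10))
        out = superpose_to_reference(traj, sel, top, sel)
        for before, after in zip(traj.frames, out.frames):
            d0 = np.linalg.norm(before[:, None] - before[None], axis=2)
            d1 = np.linalg.norm(after[:, None] - after[None], axis=2)
            np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        traj, ref, sel = self._traj_and_ref(rng)
        with pytest.raises(ValueError, match="mismatch"):
            superpose_to_reference(traj, Selection(np.arange(5)), ref, sel)


class TestTailVector:
    def _topology(self, proximal_center, distal_center):
        rows, coords = [], []
        for group, center in ((range(769, 772), proximal_center),
                              (range(784, 788), distal_center)):
            for k, resid in enumerate(group):
                for j, nm in enumerate(("N", "CA", "C")):
                    rows.append((resid, nm))
                    # offsets cancel within each group
                    off = np.array([np.cos(2.1 * (3 * k + j)), np.sin(2.1 * (3 * k + j)), 0.0])
                    coords.append(center + off - off)  # exactly at center
        return make_model(np.asarray(coords) + 0.0,
                          resid=[r for r, _ in rows], name=[n for _, n in rows])

    def test_unit_vector_between_centroids(self):
        top = self._topology(np.zeros(3), np.array([0.0, 0.0, 10.0]))
        v, p, d = tail_vector(top.coords, top)
        np.testing.assert_allclose(v, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)
        np.testing.assert_allclose(d, [0, 0, 10], atol=1e-12)

    def test_coincident_centroids_rejected(self):
        top = self._topology(np.zeros(3), np.zeros(3) + 1e-12)
        with pytest.raises(ValueError, match="zero length"):
            tail_vector(top.coords, top)

    def test_missing_atoms_listed(self):
        top = self._topology(np.zeros(3), np.array([0.0, 0.0, 10.0]))
        keep = ~((top.resid == 770) & (top.name == "CA"))
        partial = top.subset(np.where(keep)[0])
        with pytest.raises(ValueError, match="CA@770"):
            tail_vector(partial.coords, partial)


class TestComputeAngles:
    @pytest.mark.parametrize(
        "v, elevation, azimuth, tilt",
        [
            ([1, 0, 0], 90.0, 0.0, 90.0),     # along e1: degenerate azimuth
            ([0, 1, 0], 0.0, 0.0, 90.0),      # along e2
            ([0, 0, -1], 0.0, -90.0, 180.0),  # along -e3
        ],
    )
    def test_axis_aligned_conventions(self, v, elevation, azimuth, tilt):
        a = compute_tail_angles(np.array(v, float), IDENTITY_FRAME)
        assert a.elevation == pytest.approx(elevation, abs=1e-9)
        assert a.azimuth == pytest.approx(azimuth, abs=1e-9)
        assert a.tilt == pytest.approx(tilt, abs=1e-9)

    def test_degenerate_azimuth_flagged(self):
        a = compute_tail_angles(np.array([1.0, 0, 0]), IDENTITY_FRAME)
        assert a.degenerate

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_tail_angles(np.zeros(3), IDENTITY_FRAME)

    def test_invariant_under_joint_rigid_transform(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        a0 = compute_tail_angles(v, IDENTITY_FRAME)
        for _ in range(20):
            q = rng.standard_normal(4)
            rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            frame = CrossbridgeFrame(
                origin=rng.normal(size=3),
                e1=rot @ IDENTITY_FRAME.e1,
                e2=rot @ IDENTITY_FRAME.e2,
                e3=rot @ IDENTITY_FRAME.e3,
            )
            a1 = compute_tail_angles(rot @ v, frame)
            assert a1.elevation == pytest.approx(a0.elevation, abs=1e-8)
            assert a1.azimuth == pytest.approx(a0.azimuth, abs=1e-8)
            assert a1.tilt == pytest.approx(a0.tilt, abs=1e-8)

    def test_elevation_antisymmetric_under_e1_reflection(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            mirrored = v.copy()
            mirrored[0] = -mirrored[0]  # reflection through the e2-e3 plane
            a = compute_tail_angles(v, IDENTITY_FRAME)
            b = compute_tail_angles(mirrored, IDENTITY_FRAME)
            assert b.elevation == pytest.approx(-a.elevation, abs=1e-9)

    def test_tilt_supplementary_for_opposite_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            a = compute_tail_angles(v, IDENTITY_FRAME)
            b = compute_tail_angles(-v, IDENTITY_FRAME)
            assert a.tilt + b.tilt == pytest.approx(180.0, abs=1e-9)


class TestAngleRoundTrip:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.floats(min_value=-89.0, max_value=89.0),
        st.floats(min_value=-179.0, max_value=179.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_elevation_azimuth_round_trip(self, elevation, azimuth):
        """Any direction built from (elevation, azimuth) measures back to the
        same pair; tilt satisfies cos(tilt) = cos(el)·sin(az)."""
        el, az = np.radians(elevation), np.radians(azimuth)
        v = np.array([
            np.sin(el),
            np.cos(el) * np.cos(az),
            np.cos(el) * np.sin(az),
        ])
        a = compute_tail_angles(v, IDENTITY_FRAME)
        assert a.elevation == pytest.approx(elevation, abs=1e-8)
        assert a.azimuth == pytest.approx(azimuth, abs=1e-8)
        assert np.cos(np.radians(a.tilt)) == pytest.approx(
            np.cos(el) * np.sin(az), abs=1e-9
        )


class TestAngleDensity:
    def test_point_mass_density(self):
        d = angle_density(np.full(100, 35.0), bin_width=2.0)
        assert len(d.density) == 1
        assert d.density[0] == pytest.approx(0.5)

    def test_uniform_samples_approach_closed_form(self):
        rng = np.random.default_rng(7)
        samples = rng.uniform(0.0, 10.0, size=200_000)
        d = angle_density(samples, bin_width=2.0)
        occupied = d.density[d.density > 0][:5]
        np.testing.assert_allclose(occupied, 0.1, rtol=0.03)

    def test_normalization_1d_and_2d(self):
        rng = np.random.default_rng(8)
        x = rng.normal(30, 5, size=777)
        y = rng.normal(140, 7, size=777)
        d1 = angle_density(x, bin_width=2.0)
        assert np.sum(d1.density) * d1.bin_width == pytest.approx(1.0, abs=1e-9)
        d2 = angle_density(x, bin_width=2.0, samples2=y)
        area = d1.bin_width * (d2.edges2[1] - d2.edges2[0])
        assert np.sum(d2.density) * area == pytest.approx(1.0, abs=1e-9)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            angle_density([])


class TestAngleTimeseries:
    def test_constant_angles_zero_noise(self, zero_noise_apo):
        spec, system, trajs, rec = zero_noise_apo
        ref = system.reference_complex
        placed = superpose_to_reference(
            trajs[0], system.hlh_selection(), ref,
            select(ref, system.hlh_expression),
        )
        df = angle_timeseries(placed, system.frame)
        np.testing.assert_allclose(df["elevation"], spec.elevation_mean, atol=1e-9)
        np.testing.assert_allclose(df["azimuth"], spec.azimuth_mean, atol=1e-9)
        assert df["elevation"].std() < 1e-9

    def test_sample_mean_within_sampling_bound(self):
        spec = apo_spec(n_frames=4000, n_replicates=1, seed=21,
                        noise_sigma=0.0, global_motion=False,
                        saltbridge_break_elevation=None)
        system = make_hinged_system(spec)
        trajs, _ = simulate_trajectories(spec, system)
        df = angle_timeseries(trajs[0], system.frame)
        bound = 3 * spec.elevation_sd / np.sqrt(spec.n_frames)
        assert abs(df["elevation"].mean() - spec.elevation_mean) < bound

    def test_moments_invariant_under_frame_reversal(self, small_apo):
        spec, system, trajs, rec = small_apo
        traj = trajs[0]
        df = angle_timeseries(traj, system.frame)
        rev = Trajectory(topology=traj.topology, frames=traj.frames[::-1].copy(),
                         timestep=traj.timestep)
        df_rev = angle_timeseries(rev, system.frame)
        assert df["elevation"].mean() == pytest.approx(df_rev["elevation"].mean())
        assert df["elevation"].std() == pytest.approx(df_rev["elevation"].std())
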