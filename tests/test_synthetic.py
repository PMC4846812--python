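"""Tests of the vortex-filament generator against closed-form fluid mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batwake.core import ScenarioError, SequenceMeta
from batwake.synthetic import (
    FilamentWake,
    NoiseSpec,
    VortexFilament,
    build_scenario,
    ground_truth_impulse,
    induced_velocity,
    sample_plane_sequence,
)


def straight_filament(gamma=0.5, r_c=0.02, L=200.0):
    verts = np.array([[-L, 0, 0], [0, 0, 0], [L, 0, 0]], dtype=float)
    return FilamentWake(
        [VortexFilament(verts, gamma, r_c, truncated=True)], advection_speed=4.0
    )


class TestFilamentValidation:
    def test_open_polyline_rejected_unless_truncated(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(ScenarioError, match="not closed"):
            VortexFilament(verts, 0.5, 0.01)
        VortexFilament(verts, 0.5, 0.01, truncated=True)  # ok

    @pytest.mark.parametrize("gamma,r_c", [(0.0, 0.01), (np.inf, 0.01), (0.5, 0.0)])
    def test_nonphysical_parameters_rejected(self, gamma, r_c):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=float)
        with pytest.raises(ScenarioError):
            VortexFilament(verts, gamma, r_c)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ScenarioError, match="unknown scenario"):
            build_scenario("hovering_hummingbird")

    def test_single_ring_is_one_closed_loop_of_circle_area(self):
        wake = build_scenario("single_ring", dict(R=0.1, gamma=0.5))
        assert len(wake.filaments) == 1
        fil = wake.filaments[0]
        assert fil.is_closed
        # shoelace area of the polygonal loop approximates pi R^2
        v = fil.vertices
        area = 0.5 * abs(np.sum(v[:-1, 0] * v[1:, 1] - v[1:, 0] * v[:-1, 1]))
        assert area == pytest.approx(0.031416, rel=1e-3)

    def test_single_ring_rejects_nonphysical(self):
        with pytest.raises(ScenarioError):
            build_scenario("single_ring", dict(R=-0.1))
        with pytest.raises(ScenarioError):
            build_scenario("single_ring", dict(gamma=0.0))

    def test_trailing_pair_counter_rotating(self):
        wake = build_scenario("trailing_pair", dict(b=0.2, gamma=0.5))
        assert sorted(f.circulation for f in wake.filaments) == [-0.5, 0.5]

    def test_trailing_pair_net_circulation_zero(self):
        """Kelvin: the loop integral of velocity around a contour enclosing the
        whole wake cross-section vanishes for closed-loop wakes."""
        wake = build_scenario("trailing_pair", dict(b=0.2, gamma=0.5))
        # rectangular contour in the x=0 plane enclosing both in-window legs
        n = 400
        half_y, half_z = 0.5, 0.3
        top = np.column_stack(
            [np.zeros(n), np.linspace(-half_y, half_y, n), np.full(n, half_z)]
        )
        bot = np.column_stack(
            [np.zeros(n), np.linspace(half_y, -half_y, n), np.full(n, -half_z)]
        )
        right = np.column_stack(
            [np.zeros(n), np.full(n, half_y), np.linspace(half_z, -half_z, n)]
        )
        left = np.column_stack(
            [np.zeros(n), np.full(n, -half_y), np.linspace(-half_z, half_z, n)]
        )
        circ = 0.0
        for seg in (top, right, bot, left):
            vel = induced_velocity(wake, seg)
            d = np.gradient(seg, axis=0)
            circ += np.sum(np.einsum("ij,ij->i", vel, d))
        assert abs(circ) < 1e-3  # vs individual leg circulations of 0.5

    def test_reversed_loop_induces_upwash_at_its_centroid(self):
        wake = build_scenario("reversed_loop", dict(gamma=-0.1))
        vel = induced_velocity(wake, [[0.0, 0.0, 0.05]])
        assert vel[0, 2] > 0

    def test_cruise_wingbeat_tuned_to_body_weight(self):
        wake = build_scenario(
            "cruise_wingbeat", dict(U=4.0, mass=0.009, n_wingbeats=1)
        )
        # impulse of one wingbeat cell (tip + root loop) equals m g T
        T = 1.0 / 11.0
        per_cell = ground_truth_impulse(
            FilamentWake(wake.filaments[2:4], 4.0), rho=1.2
        )
        assert per_cell == pytest.approx(0.009 * 9.81 * T, rel=1e-9)


class TestInducedVelocity:
    def test_lamb_oseen_profile_of_straight_filament(self):
        wake = straight_filament(gamma=0.5, r_c=0.02)
        r = 0.1
        vel = induced_velocity(wake, [[0.0, r, 0.0]])
        expected = 0.5 / (2 * np.pi * r) * (1 - np.exp(-(r / 0.02) ** 2))
        assert np.linalg.norm(vel) == pytest.approx(expected, rel=1e-3)
        # tangential: along +z for a +x filament observed at +y
        assert vel[0, 2] == pytest.approx(expected, rel=1e-3)
        assert abs(vel[0, 0]) < 1e-12 and abs(vel[0, 1]) < 1e-12

    def test_core_regularization_keeps_velocity_finite_on_the_axis(self):
        wake = straight_filament(gamma=0.5, r_c=0.02)
        vel = induced_velocity(wake, [[0.3, 0.0, 0.0], [0.3, 1e-6, 0.0]])
        assert np.all(np.isfinite(vel))
        assert np.linalg.norm(vel[0]) < 1e-9  # exactly on the filament

    def test_ring_center_speed_gamma_over_2R(self):
        wake = build_scenario("single_ring", dict(R=0.1, gamma=0.5, center=(0, 0, 0)))
        vel = induced_velocity(wake, [[0.0, 0.0, 0.0]])
        # ring oriented for downwash inside with gamma > 0
        assert vel[0, 2] == pytest.approx(-2.5, rel=1e-3)

    def test_ring_axis_has_no_in_plane_velocity(self):
        wake = build_scenario("single_ring", dict(R=0.1, gamma=0.5, center=(0, 0, 0)))
        vel = induced_velocity(wake, [[0.0, 0.0, 0.07], [0.0, 0.0, -0.04]])
        assert np.all(np.abs(vel[:, :2]) < 1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        px=st.floats(-0.2, 0.2),
        pz=st.floats(-0.2, 0.2),
    )
    def test_linearity_in_circulation(self, scale, px, pz):
        wake = build_scenario("single_ring", dict(R=0.1, gamma=0.5, center=(0, 0, 0)))
        scaled = wake.scaled_circulation(scale)
        p = [[px, 0.03, pz]]
        np.testing.assert_allclose(
            induced_velocity(scaled, p),
            scale * induced_velocity(wake, p),
            rtol=1e-12,
            atol=1e-14,
        )

    def test_induced_field_is_divergence_free(self):
        wake = build_scenario("single_ring", dict(R=0.1, gamma=0.5, center=(0, 0, 0)))
        h = 1e-4
        p0 = np.array([0.05, 0.04, 0.06])  # away from the core
        div = 0.0
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = h
            vp = induced_velocity(wake, [p0 + e])[0, axis]
            vm = induced_velocity(wake, [p0 - e])[0, axis]
            div += (vp - vm) / (2 * h)
        grad_scale = np.linalg.norm(induced_velocity(wake, [p0])) / 0.05
        assert abs(div) < 1e-3 * max(grad_scale, 1.0)


class TestPlaneSampling:
    def test_zero_noise_samples_equal_induced_velocity(self, meta4, small_grid):
        wake = build_scenario("single_ring", dict(R=0.05, gamma=0.5, center=(0, 0, 0)))
        frames = sample_plane_sequence(
            wake, meta4, NoiseSpec(), grid=small_grid, n_frames=2
        )
        y, z = small_grid
        Y, Z = np.meshgrid(y, z, indexing="ij")
        pts = np.column_stack([np.zeros(Y.size), Y.ravel(), Z.ravel()])
        vel = induced_velocity(wake, pts)
        np.testing.assert_array_equal(frames[0].v, vel[:, 1].reshape(Y.shape))
        np.testing.assert_array_equal(frames[0].w, vel[:, 2].reshape(Y.shape))
        np.testing.assert_array_equal(frames[0].u, meta4.U + vel[:, 0].reshape(Y.shape))
        assert frames[0].valid_mask.all()
        # second frame: wake advected by U/f_L
        shifted = wake.translated((meta4.frame_spacing, 0, 0))
        vel1 = induced_velocity(shifted, pts)
        np.testing.assert_array_equal(frames[1].w, vel1[:, 2].reshape(Y.shape))

    def test_spurious_and_dropout_counts_exact(self, meta4):
        y = 0.0024 * np.arange(100)
        z = 0.0024 * np.arange(80)
        wake = build_scenario("single_ring", dict(R=0.05, gamma=0.5, center=(0, 0, 0)))
        clean = sample_plane_sequence(
            wake, meta4, NoiseSpec(), grid=(y, z), n_frames=1
        )[0]
        noisy = sample_plane_sequence(
            wake,
            meta4,
            NoiseSpec(spurious_fraction=0.05, dropout_fraction=0.02, rng_seed=7),
            grid=(y, z),
            n_frames=1,
        )[0]
        assert (noisy.u != clean.u).sum() == round(0.05 * 8000)
        assert (~noisy.valid_mask).sum() == round(0.02 * 8000)

    def test_same_seed_is_bit_identical(self, meta4, small_grid):
        wake = build_scenario("single_ring", dict(R=0.05, gamma=0.5))
        spec = NoiseSpec(velocity_noise_sd=0.04, spurious_fraction=0.05, rng_seed=11)
        a = sample_plane_sequence(wake, meta4, spec, grid=small_grid, n_frames=3)
        b = sample_plane_sequence(wake, meta4, spec, grid=small_grid, n_frames=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.u, fb.u)
            np.testing.assert_array_equal(fa.w, fb.w)
            np.testing.assert_array_equal(fa.valid_mask, fb.valid_mask)

    def test_empty_grid_rejected(self, meta4):
        wake = build_scenario("single_ring", {})
        with pytest.raises(ValueError, match="empty grid"):
            sample_plane_sequence(
                wake, meta4, grid=(np.array([]), np.array([])), n_frames=1
            )


class TestGroundTruthImpulse:
    def test_single_ring_impulse_rho_gamma_area(self):
        wake = build_scenario("single_ring", dict(R=0.1, gamma=0.5))
        assert ground_truth_impulse(wake, rho=1.2) == pytest.approx(
            1.2 * 0.5 * np.pi * 0.1**2, rel=1e-3
        )
        assert ground_truth_impulse(wake, rho=1.2) > 0  # downwash loop lifts

    def test_opposite_rings_cancel(self):
        a = build_scenario("single_ring", dict(R=0.1, gamma=0.5))
        b = build_scenario("single_ring", dict(R=0.1, gamma=-0.5))
        both = FilamentWake(a.filaments + b.filaments, 4.0)
        assert ground_truth_impulse(both) == pytest.approx(0.0, abs=1e-15)

    def test_streamwise_plane_loop_has_zero_vertical_impulse(self):
        # square loop in the x-z plane: zero horizontal projected area
        verts = np.array(
            [[0, 0, 0], [0.1, 0, 0], [0.1, 0, 0.1], [0, 0, 0.1], [0, 0, 0]],
            dtype=float,
        )
        wake = FilamentWake([VortexFilament(verts, 0.5, 0.01)], 4.0)
        assert ground_truth_impulse(wake) == pytest.approx(0.0, abs=1e-15)

    def test_truncated_filament_rejected(self):
        fil = VortexFilament(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float),
            0.5,
            0.01,
            truncated=True,
        )
        with pytest.raises(ValueError, match="closed"):
            ground_truth_impulse(FilamentWake([fil], 4.0))
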