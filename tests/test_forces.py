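"""Tests of the vorticity-moment weight-support estimator and its plumbing."""

import numpy as np
import pytest

from batwake.core import SequenceMeta
from batwake.forces import (
    ForceRecord,
    filter_sequences,
    locate_body_center,
    momentary_weight_support,
    segment_wingbeats,
    sequence_weight_support,
)
from batwake.synthetic import NoiseSpec, build_scenario, sample_plane_sequence
from tests.conftest import make_frame


def symmetric_grid(n=21, h=0.0024):
    y = h * (np.arange(n) - (n - 1) / 2)
    return y


@pytest.fixture(scope="module")
def pair_frame():
    """One noise-free frame of an ideal trailing pair (b=0.2 m, Gamma=0.5)."""
    meta = SequenceMeta(U=4.0, mass=0.009)
    wake = build_scenario("trailing_pair", dict(b=0.2, gamma=0.5, U=4.0))
    return sample_plane_sequence(wake, meta, NoiseSpec(), n_frames=1)[0], meta


class TestMomentaryWeightSupport:
    def test_ideal_pair_gives_rho_U_gamma_b(self, pair_frame):
        frame, meta = pair_frame
        F = momentary_weight_support(frame, meta, y0=0.0)
        assert F == pytest.approx(1.2 * 4.0 * 0.5 * 0.2, rel=0.01)

    def test_zero_field_gives_zero(self, meta4):
        n = 21
        y = symmetric_grid(n)
        z = symmetric_grid(15)
        zeros = np.zeros((n, 15))
        frame = make_frame(zeros, zeros, zeros, y=y, z=z)
        assert momentary_weight_support(frame, meta4, 0.0) == 0.0

    def test_left_and_right_semispans_agree_for_symmetric_wake(self, pair_frame):
        frame, meta = pair_frame
        fr = momentary_weight_support(frame, meta, 0.0, side="right")
        fl = momentary_weight_support(frame, meta, 0.0, side="left")
        fb = momentary_weight_support(frame, meta, 0.0, side="both")
        assert fl == pytest.approx(fr, rel=1e-9)
        assert fb == pytest.approx(fr, rel=1e-9)

    def test_invariant_to_uniform_velocity_offset(self, pair_frame):
        frame, meta = pair_frame
        shifted = frame.copy()
        shifted.u += 1.3
        shifted.v += 0.7
        shifted.w -= 0.2
        assert momentary_weight_support(shifted, meta, 0.0) == pytest.approx(
            momentary_weight_support(frame, meta, 0.0), rel=1e-9
        )

    def test_reversed_loop_produces_negative_momentary_force(self):
        """An upwash (reversed) loop crossing the plane registers negative
        weight support, as at the end of the upstroke."""
        meta = SequenceMeta(U=2.0, mass=0.009)
        wake = build_scenario("reversed_loop", dict(gamma=-0.1, U=2.0))
        frames = sample_plane_sequence(wake, meta, NoiseSpec())
        F = [momentary_weight_support(fr, meta, 0.0) for fr in frames]
        assert min(F) < 0

    def test_y0_outside_grid_rejected(self, pair_frame):
        frame, meta = pair_frame
        with pytest.raises(ValueError, match="outside"):
            momentary_weight_support(frame, meta, y0=1.0)

    def test_semi_span_coverage_required(self, pair_frame):
        frame, meta = pair_frame
        with pytest.raises(ValueError, match="semi-span"):
            momentary_weight_support(frame, meta, y0=float(frame.y[-1]), side="right")


class TestLocateBodyCenter:
    def test_recovers_offset_pair_center_within_half_cell(self, meta4):
        wake = build_scenario(
            "trailing_pair", dict(b=0.2, gamma=0.5, U=4.0, center_y=0.012)
        )
        frames = sample_plane_sequence(wake, meta4, NoiseSpec(), n_frames=3)
        y0 = locate_body_center(frames)
        assert abs(y0 - 0.012) <= 0.0012 + 1e-12

    def test_exact_zero_cost_at_true_plane_on_node(self, meta4):
        # center on a grid node: the antisymmetry mismatch vanishes there
        wake = build_scenario(
            "trailing_pair", dict(b=0.2, gamma=0.5, U=4.0, center_y=0.0132)
        )
        frames = sample_plane_sequence(wake, meta4, NoiseSpec(), n_frames=1)
        assert locate_body_center(frames) == pytest.approx(0.0132, abs=1e-12)

    def test_manual_override_returned_verbatim(self, meta4):
        assert locate_body_center([], override=0.0123) == 0.0123

    def test_no_wake_in_window_requires_manual_value(self, meta4):
        zeros = np.zeros((21, 15))
        frame = make_frame(zeros, zeros, zeros, y=symmetric_grid(21), z=symmetric_grid(15))
        with pytest.raises(ValueError):
            locate_body_center([frame])


class TestSegmentWingbeats:
    def test_sinusoid_period_recovered(self):
        f = np.sin(2 * np.pi * 12.0 * np.arange(640) / 640.0)
        bounds = segment_wingbeats(f, 640.0)
        lengths = [b - a for a, b in bounds]
        assert all(abs(L - 640 / 12) <= 1 for L in lengths)

    def test_square_wave_boundaries_at_rising_edges(self):
        period, n_cyc = 40, 6
        f = np.tile(np.r_[np.ones(18), np.zeros(period - 18)], n_cyc)
        bounds = segment_wingbeats(f, 640.0)
        for a, b in bounds:
            assert b - a == pytest.approx(period, abs=1)
            assert min(abs(a - k * period) for k in range(n_cyc + 1)) <= 2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="periodicity"):
            segment_wingbeats(np.full(300, 2.0), 640.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            segment_wingbeats(np.sin(np.arange(10)), 640.0)


class TestSequenceWeightSupport:
    def test_all_zero_frames_give_zero_percent(self, meta4):
        zeros = np.zeros((21, 15))
        frames = [
            make_frame(zeros, zeros, zeros, y=symmetric_grid(21), z=symmetric_grid(15), t=j / 640)
            for j in range(8)
        ]
        rec = sequence_weight_support(
            frames, meta4, y0=0.0, wingbeats=[(0, 4), (4, 8)]
        )
        assert rec.sequence_pct == 0.0
        assert not rec.accepted

    def test_doubling_circulation_doubles_weight_support(self, meta4):
        wake = build_scenario("trailing_pair", dict(b=0.2, gamma=0.5, U=4.0))
        strong = wake.scaled_circulation(2.0)
        kw = dict(noise=NoiseSpec(), n_frames=4)
        f1 = sample_plane_sequence(wake, meta4, **kw)
        f2 = sample_plane_sequence(strong, meta4, **kw)
        r1 = sequence_weight_support(f1, meta4, y0=0.0, wingbeats=[(0, 4)])
        r2 = sequence_weight_support(f2, meta4, y0=0.0, wingbeats=[(0, 4)])
        assert r2.sequence_pct == pytest.approx(2 * r1.sequence_pct, rel=1e-9)

    def test_user_intervals_take_precedence_and_are_validated(self, meta4):
        zeros = np.zeros((21, 15))
        frames = [
            make_frame(zeros, zeros, zeros, y=symmetric_grid(21), z=symmetric_grid(15), t=j / 640)
            for j in range(8)
        ]
        with pytest.raises(ValueError, match="at least 2"):
            sequence_weight_support(frames, meta4, y0=0.0, wingbeats=[(0, 1)])
        with pytest.raises(ValueError, match="overlap"):
            sequence_weight_support(
                frames, meta4, y0=0.0, wingbeats=[(0, 5), (3, 8)]
            )

    def test_meta_body_center_override_used(self, meta4):
        meta = SequenceMeta(U=4.0, mass=0.009, body_center_y=0.0)
        wake = build_scenario("trailing_pair", dict(b=0.2, gamma=0.5, U=4.0))
        frames = sample_plane_sequence(wake, meta, NoiseSpec(), n_frames=4)
        rec = sequence_weight_support(frames, meta, wingbeats=[(0, 4)])
        assert rec.body_center_y == 0.0


class TestFilterSequences:
    def make_record(self, pct):
        return ForceRecord(
            time=np.zeros(1), momentary_force=np.zeros(1), wingbeat_bounds=[(0, 1)],
            wingbeat_mean_force=np.zeros(1), weight_support_pct=np.array([pct]),
            sequence_pct=pct, accepted=abs(pct - 100) <= 20, body_center_y=0.0,
        )

    def test_inclusive_twenty_percent_band(self):
        records = [self.make_record(p) for p in (75.0, 85.0, 100.0, 125.0)]
        kept = filter_sequences(records)
        assert [r.sequence_pct for r in kept] == [85.0, 100.0]

    @pytest.mark.parametrize("pct,kept", [(120.0, True), (121.0, False), (80.0, True), (99.0, True)])
    def test_boundaries(self, pct, kept):
        assert bool(filter_sequences([self.make_record(pct)])) is kept
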