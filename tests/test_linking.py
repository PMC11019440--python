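"""Frame linking, gap closing, interpolation and anomalous-jump splitting."""

import numpy as np
import pytest

from casatrack import (Detection, Track, build_tracks,
                       close_gaps, interpolate_gaps, link_frames,
                       split_anomalous, track_pipeline, simulate_tracks,
                       degrade_detections)
from conftest import brute_force_assignment, lane_specs


def dets(points, frame=0):
    return [Detection(frame_index=frame, x=float(x), y=float(y))
            for x, y in points]


class TestLinkFrames:
    def test_single_close_pair_links(self):
        a = link_frames(dets([(0, 0)]), dets([(1 / 0.325, 0)], 1), 4.2, 0.325)
        assert a.pairs == [(0, 0)]
        assert a.total_cost == pytest.approx(1.0)

    def test_distance_gate_forbids_far_pair(self):
        a = link_frames(dets([(0, 0)]), dets([(10 / 0.325, 0)], 1), 4.2, 0.325)
        assert a.pairs == [] and a.unmatched_prev == [0] and a.unmatched_next == [0]

    def test_empty_inputs_yield_empty_assignment(self):
        a = link_frames([], dets([(1, 1)]), 4.2, 1.0)
        assert a.pairs == [] and a.unmatched_next == [0]

    def test_matches_bruteforce_on_random_instances(self):
        """Hungarian matches exhaustive enumeration (max pairs, min cost)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, m = rng.integers(0, 5, size=2)
            prev_xy = rng.uniform(0, 10, size=(n, 2))
            next_xy = rng.uniform(0, 10, size=(m, 2))
            a = link_frames(dets(prev_xy), dets(next_xy, 1), 4.2, 1.0)
            bf_matches, bf_cost = brute_force_assignment(prev_xy, next_xy, 4.2)
            assert len(a.pairs) == bf_matches
            assert a.total_cost == pytest.approx(bf_cost, abs=1e-9)

    def test_keeps_identities_where_greedy_would_swap(self):
        """Two swimmers advancing in file: nearest-first pairing links the
        trailing head backwards; the global optimum keeps both identities."""
        prev_xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        next_xy = np.array([[0.55, 0.0], [1.55, 0.0]])
        a = link_frames(dets(prev_xy), dets(next_xy, 1), 4.2, 1.0)
        assert sorted(a.pairs) == [(0, 0), (1, 1)]
        # sanity: the greedy-favourite swap pair is indeed locally closer
        assert np.linalg.norm(prev_xy[1] - next_xy[0]) < 0.55
        bf_matches, bf_cost = brute_force_assignment(prev_xy, next_xy, 4.2)
        assert a.total_cost == pytest.approx(bf_cost, abs=1e-12)


class TestBuildTracks:
    def test_two_parallel_swimmers_give_two_full_tracks(self, params):
        frames = [dets([(t, 10), (t, 50)], t) for t in range(20)]
        tracks = build_tracks(frames, params)
        assert len(tracks) == 2
        assert all(t.n_points == 20 for t in tracks)

    def test_singleton_detection_no_track(self, params):
        frames = [dets([(5, 5)], 0), [], []]
        assert build_tracks(frames, params) == []

    def test_detection_conservation(self, params):
        """Track points are distinct real detections; the remainder of the
        detection budget is unlinked singletons."""
        rng = np.random.default_rng(1)
        frames = [dets(rng.uniform(0, 100, size=(6, 2)), t) for t in range(15)]
        total = sum(len(f) for f in frames)
        available = {(t, float(d.x), float(d.y))
                     for t, fr in enumerate(frames) for d in fr}
        tracks = build_tracks(frames, params)
        used = []
        for t in tracks:
            for f, (x, y) in zip(t.frames, t.xy):
                used.append((int(f), float(x), float(y)))
        assert len(used) == len(set(used))          # no detection reused
        assert set(used) <= available               # all points are real
        assert len(used) + (total - len(used)) == total


class TestCloseGaps:
    def _broken(self, gap, step_px=1.0):
        a = Track(0, np.arange(0, 5), np.column_stack([np.arange(5.0) * step_px,
                                                       np.zeros(5)]))
        start = 5 + gap
        xs = (np.arange(start, start + 5)) * step_px
        b = Track(1, np.arange(start, start + 5),
                  np.column_stack([xs, np.zeros(5)]))
        return [a, b]

    def test_single_frame_gap_restored(self, params):
        out = close_gaps(self._broken(gap=1), params)
        assert len(out) == 1
        assert out[0].frames[0] == 0 and out[0].frames[-1] == 10

    def test_gap_beyond_frame_budget_not_merged(self, params):
        out = close_gaps(self._broken(gap=params.gap_max_frames + 1), params)
        assert len(out) == 2

    def test_distant_ends_not_merged(self, params):
        # 20 um jump across a 1-frame gap exceeds the 8.5 um budget
        out = close_gaps(self._broken(gap=1, step_px=10.0 / 0.325), params)
        assert len(out) == 2

    def test_chain_of_fragments_merges_fully(self, params):
        a, b = self._broken(gap=1)
        c = Track(2, np.arange(12, 17),
                  np.column_stack([np.arange(12.0, 17.0), np.zeros(5)]))
        out = close_gaps([a, b, c], params)
        assert len(out) == 1 and out[0].frames[-1] == 16


class TestInterpolateGaps:
    def test_midpoint_fill(self):
        t = Track(0, [0, 2], [[0.0, 0.0], [2.0, 0.0]])
        out = interpolate_gaps(t)
        assert list(out.frames) == [0, 1, 2]
        assert out.xy[1] == pytest.approx([1.0, 0.0])
        assert list(out.interpolated) == [False, True, False]

    def test_gapless_track_unchanged(self):
        t = Track(0, [0, 1, 2], [[0, 0], [1, 0], [2, 0]])
        assert interpolate_gaps(t) is t

    def test_three_frame_gap_linear_fill(self):
        t = Track(0, [0, 4], [[0.0, 0.0], [4.0, 8.0]])
        out = interpolate_gaps(t)
        assert out.n_points == 5
        assert out.xy[:, 1] == pytest.approx([0, 2, 4, 6, 8])
        assert out.interpolated[1:4].all()


class TestSplitAnomalous:
    def test_uniform_steps_unchanged(self):
        t = Track(0, np.arange(50), np.column_stack([np.arange(50.0),
                                                     np.zeros(50)]))
        assert split_anomalous(t, 5.0) == [t]

    def test_single_big_jump_splits_in_two(self):
        # 50 unit steps, one 10 px jump, 50 unit steps -> mean ~1.09, 10 > 5x
        x = np.concatenate([np.arange(51.0), np.arange(51.0) + 60.0])
        t = Track(0, np.arange(102), np.column_stack([x, np.zeros(102)]))
        steps = t.step_lengths()
        assert steps.mean() == pytest.approx((50 + 10 + 50) / 101)
        pieces = split_anomalous(t, 5.0)
        assert [p.n_points for p in pieces] == [51, 51]

    def test_two_point_track_never_split(self):
        t = Track(0, [0, 1], [[0.0, 0.0], [100.0, 0.0]])
        assert split_anomalous(t, 5.0) == [t]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.uniform(-1, 1, size=(200, 2)), axis=0)
        xy[100] += 50.0
        t = Track(0, np.arange(200), xy)
        once = split_anomalous(t, 5.0)
        again = [p for piece in once for p in split_anomalous(piece, 5.0)]
        assert len(again) == len(once)
        for a, b in zip(once, again):
            assert np.array_equal(a.xy, b.xy)


class TestTrackRecovery:
    def test_dropout_tracks_recovered_single(self, params):
        """With 5% per-detection dropout, swimmers whose realized gaps stay
        within the closing budgets are recovered as one track each."""
        field = (400.0, 400.0)
        speeds = np.linspace(30, 200, 24)
        specs = lane_specs(list(speeds), field, seed=9)
        gt = simulate_tracks(specs, 10.0, 100.0, seed=9, field_um=field)
        clean = gt.detections_by_frame(params.um_per_pixel)
        noisy = degrade_detections(clean, dropout_prob=0.05, seed=10,
                                   field_shape_px=(1231, 1231))
        tracks = track_pipeline(noisy, params)

        recoverable = recovered = 0
        for i in range(gt.n_swimmers):
            # closable iff every realized dropout run fits both budgets
            present = np.array([any(abs(d.x - gt.xy_um[i, k, 0] / params.um_per_pixel) < 1e-6
                                    for d in noisy[k]) for k in range(1000)])
            ok = True
            runs = np.flatnonzero(np.diff(np.concatenate([[1], present, [1]])))
            for s, e in zip(runs[::2], runs[1::2]):
                if s == 0 or e == len(present):
                    continue  # truncation at the ends, not an internal gap
                gap = e - s
                jump = np.linalg.norm(gt.xy_um[i, e] - gt.xy_um[i, s - 1])
                if gap > params.gap_max_frames or jump > params.gap_max_distance:
                    ok = False
            if not ok:
                continue
            recoverable += 1
            for t in tracks:
                k0, k1 = int(t.frames[0]), int(t.frames[-1])
                seg = gt.xy_um[i, k0:k1 + 1] / params.um_per_pixel
                if (t.n_points >= 950
                        and np.linalg.norm(seg - t.xy, axis=1).mean() < 2.0):
                    recovered += 1
                    break
        assert recoverable >= 20
        assert recovered / recoverable >= 0.95

    def test_gap_closing_never_decreases_frames(self, params):
        specs = lane_specs([60, 120, 180], (100.0, 100.0), seed=11)
        gt = simulate_tracks(specs, 2.0, 100.0, seed=11, field_um=(100.0, 100.0))
        noisy = degrade_detections(gt.detections_by_frame(params.um_per_pixel),
                                   dropout_prob=0.1, seed=12)
        for t in track_pipeline(noisy, params):
            assert (np.diff(t.frames) == 1).all()
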