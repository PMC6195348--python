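"""Tracker unit tests: background model, contour selection, zones, entries."""

import numpy as np
import pytest

from phenotrack import synth
from phenotrack.tracking import (
    ArenaGeometry,
    TrackerParams,
    Trajectory,
    build_background,
    classify_epm_entries,
    entry_commitment,
    occupancy_and_entrances,
    track_frame,
    track_video,
)


def blob_frame(shape, cx, cy, value=200.0, radius=8):
    """Frame with a filled bright disk on a zero background."""
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = value
    return img


class TestBackground:
    def test_constant_frames_give_constant_background(self):
        frames = np.full((5, 20, 30), 37.0)
        assert np.allclose(build_background(frames), 37.0)

    def test_mean_of_two_frames(self):
        frames = np.stack([np.zeros((10, 10)), np.full((10, 10), 100.0)])
        # sigma=0 disables the filter so the pixel-wise mean is exposed
        assert np.allclose(build_background(frames, sigma=0.0), 50.0)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            build_background(np.empty((0, 10, 10)))

    def test_background_converges_to_truth_at_185_frames(self):
        rng = np.random.default_rng(0)
        truth = np.full((40, 60), 30.0)
        noise_sd = 2.0
        frames = truth + rng.normal(0, noise_sd, (185, 40, 60))
        bg = build_background(frames, sigma=2.0)
        assert np.max(np.abs(bg - truth)) < noise_sd


class TestTrackFrame:
    def test_single_blob_detected_near_truth(self, box_arena):
        shape = (200, 300)
        frame = blob_frame(shape, 200, 150)
        pos, validity = track_frame(
            frame, np.zeros(shape), TrackerParams(threshold=50),
            previous=(198, 150), arena=box_arena,
        )
        assert validity == "detected"
        # oracle: intensity-weighted centroid of the thresholded mask
        mask = frame > 50
        yy, xx = np.nonzero(mask)
        assert np.hypot(pos[0] - xx.mean(), pos[1] - yy.mean()) < 2.0

    def test_jump_beyond_limit_returns_previous_inferred(self, box_arena):
        shape = (200, 300)
        frame = blob_frame(shape, 250, 100)
        pos, validity = track_frame(
            frame, np.zeros(shape), TrackerParams(threshold=50),
            previous=(100, 100), arena=box_arena,  # 150 px away
        )
        assert validity == "inferred"
        assert pos == (100, 100)

    def test_frame_equal_to_background_is_inferred(self, box_arena):
        bg = np.full((200, 300), 40.0)
        pos, validity = track_frame(
            bg.copy(), bg, TrackerParams(threshold=25),
            previous=(50, 60), arena=box_arena,
        )
        assert (pos, validity) == ((50, 60), "inferred")

    def test_no_previous_and_no_contour_is_undefined(self, box_arena):
        bg = np.zeros((200, 300))
        pos, validity = track_frame(
            bg.copy(), bg, TrackerParams(threshold=25), previous=None,
            arena=box_arena,
        )
        assert pos is None and validity == "undefined"

    def test_contour_outside_bounds_rejected(self):
        arena = ArenaGeometry(bounds=[(0, 0), (100, 0), (100, 200), (0, 200)])
        frame = blob_frame((200, 300), 200, 100)  # blob beyond x=100
        pos, validity = track_frame(
            frame, np.zeros((200, 300)), TrackerParams(threshold=50),
            previous=(90, 100), arena=arena,
        )
        assert validity == "inferred" and pos == (90, 100)

    def test_exclusion_area_rejected(self, box_arena):
        arena = ArenaGeometry(
            bounds=box_arena.bounds, zones=box_arena.zones,
            exclusions=[[(180, 130), (220, 130), (220, 170), (180, 170)]],
            px_per_cm=4.0,
        )
        frame = blob_frame((200, 300), 200, 150)
        pos, validity = track_frame(
            frame, np.zeros((200, 300)), TrackerParams(threshold=50),
            previous=(100, 100), arena=arena,
        )
        assert validity == "inferred"

    def test_equal_area_tie_goes_to_nearest_previous(self, box_arena):
        shape = (200, 300)
        frame = blob_frame(shape, 60, 100) + blob_frame(shape, 240, 100)
        pos, validity = track_frame(
            frame, np.zeros(shape), TrackerParams(threshold=50, jump_limit=300),
            previous=(70, 100), arena=box_arena,
        )
        assert validity == "detected"
        assert abs(pos[0] - 60) < 2

    def test_largest_area_contour_wins(self, box_arena):
        shape = (200, 300)
        frame = blob_frame(shape, 60, 100, radius=12) + blob_frame(
            shape, 120, 100, radius=5
        )
        pos, _ = track_frame(
            frame, np.zeros(shape), TrackerParams(threshold=50, jump_limit=300),
            previous=(110, 100), arena=box_arena,
        )
        assert abs(pos[0] - 60) < 2


class TestTrackVideo:
    def test_output_length_and_validity_invariants(self, box_arena):
        config = synth.SynthConfig(seed=3, frame_shape=(200, 300))
        traj = synth.random_trajectory(config, box_arena, 120)
        bg, frames = synth.make_arena_video(config, traj, box_arena)
        out = track_video(frames, build_background(bg),
                          TrackerParams(threshold=25), box_arena, 50.0)
        assert len(out) == len(frames)
        for x, y, v in zip(out.x, out.y, out.valid):
            if v == "detected":
                assert box_arena.in_bounds(x, y)
        # inferred positions repeat the last detected one
        last = None
        for x, y, v in zip(out.x, out.y, out.valid):
            if v == "detected":
                last = (x, y)
            elif v == "inferred":
                assert (x, y) == last


class TestOccupancy:
    def test_time_in_single_zone(self, box_arena):
        n = 500
        traj = Trajectory(
            t=np.arange(n) / 50.0, x=np.full(n, 150.0), y=np.full(n, 100.0),
            valid=np.full(n, "detected", dtype=object), frame_rate=50.0,
        )
        res = occupancy_and_entrances(traj, box_arena)
        assert res["time_s"]["chamber"] == pytest.approx(10.0)
        assert res["entrances"]["chamber"] == 1  # the initial entry

    def test_straight_path_distance(self, box_arena):
        n = 100
        traj = Trajectory(
            t=np.arange(n) / 50.0, x=np.linspace(0, 400, n) % 300,
            y=np.full(n, 100.0), valid=np.full(n, "detected", dtype=object),
            frame_rate=50.0,
        )
        # use a simple monotone path instead: 0 -> 400 needs a larger arena
        arena = ArenaGeometry(bounds=[(0, 0), (500, 0), (500, 200), (0, 200)],
                              px_per_cm=4.0)
        traj = Trajectory(
            t=np.arange(n) / 50.0, x=np.linspace(0, 400, n),
            y=np.full(n, 100.0), valid=np.full(n, "detected", dtype=object),
            frame_rate=50.0,
        )
        res = occupancy_and_entrances(traj, arena)
        assert res["distance_cm"] == pytest.approx(100.0)

    def test_planted_entry_count_recovered(self):
        arena = synth.ymaze_arena()
        left = arena.zone_polygon("left_arm").centroid
        center = arena.zone_polygon("center").centroid
        pts = []
        for _ in range(7):
            pts += [(center.x, center.y), (left.x, left.y)]
        pts.append((center.x, center.y))
        traj = synth.waypoint_trajectory(pts, n_frames=1400, frame_rate=50.0)
        res = occupancy_and_entrances(traj, arena)
        assert res["entrances"]["left_arm"] == 7

    def test_zone_times_sum_to_duration(self, box_arena):
        config = synth.SynthConfig(seed=9, frame_shape=(200, 300))
        traj = synth.random_trajectory(config, box_arena, 300)
        res = occupancy_and_entrances(traj, box_arena)
        total = sum(res["time_s"].values()) + res["out_of_zone_s"]
        assert total == pytest.approx(res["duration_s"], abs=1 / 50.0)

    def test_empty_trajectory_rejected(self, box_arena):
        traj = Trajectory(t=np.empty(0), x=np.empty(0), y=np.empty(0),
                          valid=np.empty(0, dtype=object), frame_rate=50.0)
        with pytest.raises(ValueError):
            occupancy_and_entrances(traj, box_arena)


class TestEpmEntries:
    @pytest.fixture
    def arena(self):
        return synth.epm_arena(px_per_cm=4.0)

    def _excursion(self, arena, depth_cm):
        """Center -> open arm to the given depth -> back to center."""
        c = arena.zone_polygon("center").centroid
        arm = arena.zone_polygon("open_n")
        # arm extends upward (smaller y) from the center
        entry_y = arena.zone_polygon("center").bounds[1]
        target = (c.x, entry_y - depth_cm * arena.px_per_cm - 1)
        assert arm.covers(type(c)(target))
        pts = [(c.x, c.y), target, (c.x, c.y)]
        return synth.waypoint_trajectory(pts, n_frames=200, frame_rate=50.0)

    def test_deep_entry_is_full(self, arena):
        traj = self._excursion(arena, depth_cm=20.0)
        counts = classify_epm_entries(traj, arena, full_depth_cm=4.0)
        assert counts["open"] == {"full": 1, "jittery": 0}

    def test_shallow_entry_is_jittery(self, arena):
        traj = self._excursion(arena, depth_cm=1.0)
        counts = classify_epm_entries(traj, arena, full_depth_cm=4.0)
        assert counts["open"] == {"full": 0, "jittery": 1}

    def test_commitment_arithmetic(self):
        assert entry_commitment(3, 1) == pytest.approx(0.75)
        assert np.isnan(entry_commitment(0, 0))
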