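"""Social assays: tracks, contact epochs, interaction labels, three-chamber."""

import numpy as np
import pytest

from behavekin.social import (
    ArenaLayout,
    Track2D,
    build_tracks,
    classify_interactions,
    detect_close_contacts,
    pair_distance_series,
    three_chamber_report,
)
from behavekin.synthetic import (
    SceneScript,
    VisitEvent,
    default_social_script,
    default_three_chamber_layout,
    simulate_social_session,
    simulate_three_chamber,
    switch_social_script,
)


def _track(points, identity="A", label="body", fps=30.0):
    points = np.asarray(points, dtype=float)
    return Track2D(identity, label, fps, np.arange(len(points)), points)


class TestBuildTracks:
    def test_eight_classes_give_eight_tracks(self, social_class_map):
        sess = simulate_social_session(default_social_script(seed=1))
        tracks = build_tracks(sess.table(), social_class_map, px_per_cm=20.0, fps=30.0)
        assert len(tracks) == 8
        assert {(t.identity, t.label) for t in tracks} == set(social_class_map.values())

    def test_pixel_to_cm_scale_arithmetic(self, social_class_map):
        # 45x45 cm arena spanning 900 px -> 20 px/cm; 90 px displacement = 4.5 cm
        sess = simulate_social_session(default_social_script(seed=2))
        tracks = build_tracks(sess.table(), social_class_map, px_per_cm=20.0, fps=30.0)
        t0 = tracks[0]
        px = t0.points * 20.0
        moved = px + 90.0
        assert np.allclose(moved / 20.0 - t0.points, 4.5)

    def test_unmapped_label_warns_and_skips(self, social_class_map):
        sess = simulate_social_session(default_social_script(seed=3))
        partial = {k: v for k, v in social_class_map.items() if "tail" not in k}
        with pytest.warns(UserWarning):
            tracks = build_tracks(sess.table(), partial, 20.0, fps=30.0)
        assert len(tracks) == 6


class TestPairDistance:
    def test_identical_tracks_zero(self):
        pts = np.random.default_rng(0).uniform(0, 45, (50, 2))
        assert np.allclose(pair_distance_series(_track(pts), _track(pts, "B")), 0.0)

    def test_parallel_offset_three_four_five(self):
        pts = np.cumsum(np.ones((40, 2)), axis=0)
        d = pair_distance_series(_track(pts), _track(pts + [3.0, 4.0], "B"))
        assert np.allclose(d, 5.0)

    def test_fps_mismatch_raises(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            pair_distance_series(_track(pts, fps=30.0), _track(pts, "B", fps=25.0))


class TestContactEpochs:
    def test_never_below_threshold_gives_no_epochs(self):
        dist = np.full(300, 20.0)
        assert detect_close_contacts(dist, fps=30.0, threshold_cm=10.0) == []

    def test_short_bout_is_dropped(self):
        dist = np.full(300, 20.0)
        dist[100:114] = 5.0  # 14 frames < 0.5 s at 30 fps
        assert detect_close_contacts(dist, fps=30.0, threshold_cm=10.0,
                                     min_duration_s=0.5) == []

    def test_scripted_bouts_recovered_exactly(self, social_class_map):
        script = default_social_script(seed=4)
        sess = simulate_social_session(script)
        tracks = build_tracks(sess.table(), social_class_map, 20.0, fps=30.0)
        bodies = {t.identity: t for t in tracks if t.label == "body"}
        dist = pair_distance_series(bodies["A"], bodies["B"])
        epochs = detect_close_contacts(dist, fps=30.0, threshold_cm=10.0)
        assert len(epochs) == len(script.events)
        # ground-truth epochs from true tracks
        gt_bodies = {t.identity: t for t in sess.truth_tracks if t.label == "body"}
        gt_dist = pair_distance_series(gt_bodies["A"], gt_bodies["B"])
        gt_epochs = detect_close_contacts(gt_dist, fps=30.0, threshold_cm=10.0)
        for got, want in zip(epochs, gt_epochs):
            assert abs(got.start_frame - want.start_frame) <= 2
            assert abs(got.end_frame - want.end_frame) <= 2

    def test_epoch_conservation_accounting(self):
        rng = np.random.default_rng(5)
        dist = rng.uniform(5, 15, 1000)
        thr = 10.0
        epochs = detect_close_contacts(dist, fps=30.0, threshold_cm=thr,
                                       min_duration_s=0.2, merge_gap_s=0.0)
        in_contact = int((dist < thr).sum())
        epoch_frames = sum(e.n_frames for e in epochs)
        # epochs only ever contain below-threshold frames (merge gap 0)
        # and dropped runs account for the rest
        from behavekin.trajectory import gap_runs
        dropped = sum(b - a for a, b in gap_runs(dist < thr)
                      if b - a < 0.2 * 30.0)
        assert epoch_frames + dropped == in_contact

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        dist = rng.uniform(0, 30, 2000)
        totals = []
        for thr in (5.0, 10.0, 15.0, 20.0):
            eps = detect_close_contacts(dist, fps=30.0, threshold_cm=thr,
                                        min_duration_s=0.0, merge_gap_s=0.0)
            totals.append(sum(e.n_frames for e in eps))
        assert totals == sorted(totals)


class TestClassifyInteractions:
    def test_scripted_modes_recovered(self, social_class_map):
        script = default_social_script(seed=7)
        sess = simulate_social_session(script)
        tracks = build_tracks(sess.table(), social_class_map, 20.0, fps=30.0)
        bodies = {t.identity: t for t in tracks if t.label == "body"}
        epochs = detect_close_contacts(pair_distance_series(bodies["A"], bodies["B"]),
                                       fps=30.0, threshold_cm=10.0)
        agree = total = 0
        for ep in epochs:
            classify_interactions(ep, tracks, nose_contact_cm=3.0)
            for j, lab in enumerate(ep.labels):
                gt = sess.truth_labels[ep.start_frame + j]
                if gt:
                    total += 1
                    agree += lab == gt
        assert total > 0
        assert agree / total >= 0.95

    def test_mode_switch_detected_once_near_script_time(self, social_class_map):
        script = switch_social_script(seed=8)
        sess = simulate_social_session(script)
        tracks = build_tracks(sess.table(), social_class_map, 20.0, fps=30.0)
        bodies = {t.identity: t for t in tracks if t.label == "body"}
        epochs = detect_close_contacts(pair_distance_series(bodies["A"], bodies["B"]),
                                       fps=30.0, threshold_cm=10.0)
        assert len(epochs) == 1
        ep = classify_interactions(epochs[0], tracks, nose_contact_cm=3.0)
        modes = [(ep.start_frame + j, lab) for j, lab in enumerate(ep.labels)
                 if lab not in ("proximity_only", "unclassified")]
        seq = [m for _, m in modes]
        switches = [k for k in range(1, len(seq)) if seq[k] != seq[k - 1]]
        assert len(switches) == 1
        switch_frame = modes[switches[0]][0]
        assert abs(switch_frame - script.events[1].start_s * script.fps) <= 3
        assert seq[0] == "noseB-tailA" and seq[-1] == "nose-nose"

    def test_far_pairs_give_proximity_only(self):
        n = 40
        tracks = []
        for ident, x in (("A", 0.0), ("B", 8.0)):
            for part, off in (("nose", 1.0), ("body", 0.0), ("tail", -1.0)):
                pts = np.tile([x + off, 0.0], (n, 1))
                tracks.append(_track(pts, ident, part))
        dist = pair_distance_series(tracks[1], tracks[4])
        ep = detect_close_contacts(dist, fps=30.0, threshold_cm=10.0)[0]
        classify_interactions(ep, tracks, nose_contact_cm=3.0)
        assert set(ep.labels) == {"proximity_only"}


class TestThreeChamber:
    def test_parked_head_counting(self):
        layout = default_three_chamber_layout()
        pts = np.tile(layout.cup_centers["left"], (300, 1))
        rep = three_chamber_report(_track(pts, label="head"), layout)
        assert rep.cup_time_s["left"] == pytest.approx(10.0)
        assert rep.cup_time_s["right"] == 0.0

    def test_scripted_split_is_exact(self):
        layout = default_three_chamber_layout()
        script = SceneScript(seed=9, fps=30.0, duration_s=210.0,
                             events=[VisitEvent("left", 10.0, 130.0),
                                     VisitEvent("right", 140.0, 200.0)])
        sess = simulate_three_chamber(layout, script)
        rep = three_chamber_report(sess.truth_track, layout)
        assert rep.cup_pct_of_interaction["left"] == pytest.approx(200.0 / 3.0)
        assert rep.cup_pct_of_interaction["right"] == pytest.approx(100.0 / 3.0)

    def test_chamber_transitions_counted(self):
        layout = default_three_chamber_layout()
        xs = np.concatenate([np.full(30, 10.0), np.full(30, 30.0),
                             np.full(30, 50.0), np.full(30, 30.0)])
        pts = np.column_stack([xs, np.full_like(xs, 10.0)])
        rep = three_chamber_report(_track(pts, label="head"), layout)
        assert rep.transition_count == 3

    def test_empty_track_raises(self):
        layout = default_three_chamber_layout()
        empty = Track2D("s", "head", 30.0, np.array([], dtype=int), np.empty((0, 2)))
        with pytest.raises(ValueError):
            three_chamber_report(empty, layout)


class TestRigidInvariance:
    def test_translation_rotation_leave_report_unchanged(self):
        layout = default_three_chamber_layout()
        script = SceneScript(seed=10, fps=30.0, duration_s=60.0,
                             events=[VisitEvent("left", 10.0, 40.0)])
        sess = simulate_three_chamber(layout, script)
        rep0 = three_chamber_report(sess.truth_track, layout)

        th = np.radians(30.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([7.0, -3.0])
        moved_pts = sess.truth_track.points @ R.T + shift
        moved_track = Track2D("s", "head", 30.0, sess.truth_track.frames, moved_pts)
        moved_layout = ArenaLayout(
            layout.arena_width + 20, layout.arena_height + 20, layout.px_per_cm,
            {k: tuple(np.asarray(v) @ R.T + shift) for k, v in layout.cup_centers.items()},
            layout.cup_radius, layout.interact_margin, [])
        rep1 = three_chamber_report(moved_track, moved_layout)
        assert rep1.cup_time_s == pytest.approx(rep0.cup_time_s)
        assert rep1.bout_count == rep0.bout_count
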