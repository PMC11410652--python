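"""Thresholding, blob extraction, background modelling and track linking."""
import itertools
from collections import Counter

import numpy as np
import pytest

from heatseek import tracker
from heatseek.tracker import (BackgroundModel, Detection, FrameStack,
                              build_background_model, detect_blobs,
                              foreground_mask, link_detections, threshold_mask)


def _stack(frames, fps=10.0):
    return FrameStack(np.asarray(frames, dtype=np.uint8), fps)


class TestBackgroundModel:
    def test_constant_stack_returns_any_frame(self):
        frame = np.full((4, 5), 173, np.uint8)
        stack = _stack([frame] * 8)
        bg = build_background_model(stack, n_samples=8, seed=0)
        assert np.array_equal(bg.image, frame)

    def test_majority_value_wins(self):
        frames = [np.full((2, 2), 100, np.uint8)] * 60 + [np.full((2, 2), 200, np.uint8)] * 40
        bg = build_background_model(_stack(frames), n_samples=100, seed=1)
        assert np.all(bg.image == 100)

    def test_tie_breaks_to_lower_value(self):
        # exhaustive over two-frame stacks of scalar pixels: a 50/50 tie
        # must resolve to the lower intensity
        for a, b in itertools.product([0, 13, 50, 200, 255], repeat=2):
            stack = _stack([np.full((1, 1), a), np.full((1, 1), b)])
            bg = build_background_model(stack, n_samples=2, seed=0)
            assert bg.image[0, 0] == min(a, b)

    def test_matches_bruteforce_mode_on_random_stacks(self):
        # independent oracle: per-pixel Counter mode with lowest-value tie-break
        rng = np.random.default_rng(7)
        for _ in range(10):
            frames = rng.integers(0, 5, size=(9, 4, 6)).astype(np.uint8)
            bg = build_background_model(_stack(frames), n_samples=9, seed=0)
            for i in range(4):
                for j in range(6):
                    counts = Counter(frames[:, i, j].tolist())
                    top = max(counts.values())
                    expected = min(v for v, c in counts.items() if c == top)
                    assert bg.image[i, j] == expected

    def test_empty_stack_errors(self):
        stack = FrameStack(np.empty((0, 3, 3), np.uint8), 10.0)
        with pytest.raises(ValueError):
            build_background_model(stack)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 255, size=(50, 6, 6)).astype(np.uint8)
        a = build_background_model(_stack(frames), n_samples=10, seed=5)
        b = build_background_model(_stack(frames), n_samples=10, seed=5)
        assert np.array_equal(a.image, b.image)


class TestMasks:
    def test_identical_frame_gives_empty_foreground(self):
        frame = np.random.default_rng(0).integers(0, 255, (5, 5)).astype(np.uint8)
        assert not foreground_mask(frame, BackgroundModel(frame)).any()

    @pytest.mark.parametrize("diff,expected", [(31, 1), (30, 0), (29, 0)])
    def test_delta_inequality_is_strict(self, diff, expected):
        bg = BackgroundModel(np.full((4, 4), 100, np.uint8))
        frame = np.full((4, 4), 100, np.uint8)
        frame[2, 3] = 100 + diff
        assert foreground_mask(frame, bg, delta=30).sum() == expected

    def test_foreground_dimension_mismatch(self):
        with pytest.raises(ValueError):
            foreground_mask(np.zeros((3, 3), np.uint8),
                            BackgroundModel(np.zeros((4, 4), np.uint8)))

    def test_threshold_mask_dark_object_convention(self):
        light = np.full((6, 6), 220, np.uint8)
        assert not threshold_mask(light, 128).any()
        frame = light.copy()
        frame[1:6, 0:5] = 40
        assert threshold_mask(frame, 128).sum() == 25
        assert not threshold_mask(frame, 0).any()


class TestDetectBlobs:
    def test_square_block_centroid_and_area(self):
        mask = np.zeros((40, 40), bool)
        mask[10:15, 20:25] = True  # top-left pixel at (x=20, y=10)
        dets = detect_blobs(mask, frame_index=7)
        assert dets == [Detection(7, 22.0, 12.0, 25)]

    def test_empty_mask(self):
        assert detect_blobs(np.zeros((5, 5), bool)) == []

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((6, 6), bool)
        mask[1:3, 1:3] = True
        mask[3:5, 3:5] = True  # touches only at the (2,2)-(3,3) diagonal
        assert len(detect_blobs(mask)) == 1

    def test_matches_floodfill_oracle_on_random_masks(self):
        def flood_components(mask):
            seen = np.zeros_like(mask, bool)
            comps = []
            H, W = mask.shape
            for i in range(H):
                for j in range(W):
                    if mask[i, j] and not seen[i, j]:
                        stack, comp = [(i, j)], []
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            comp.append((a, b))
                            for da in (-1, 0, 1):
                                for db in (-1, 0, 1):
                                    na, nb = a + da, b + db
                                    if 0 <= na < H and 0 <= nb < W and mask[na, nb] \
                                            and not seen[na, nb]:
                                        seen[na, nb] = True
                                        stack.append((na, nb))
                        comps.append(comp)
            return comps

        rng = np.random.default_rng(11)
        for _ in range(15):
            mask = rng.random((12, 14)) < 0.3
            dets = detect_blobs(mask)
            comps = flood_components(mask)
            assert len(dets) == len(comps)
            got = sorted((d.area, round(d.x, 9), round(d.y, 9)) for d in dets)
            want = sorted(
                (len(c), round(np.mean([b for _, b in c]), 9),
                 round(np.mean([a for a, _ in c]), 9))
                for c in comps
            )
            assert got == want


def _dets(points_by_frame):
    return [[Detection(f, x, y, 10) for (x, y) in pts]
            for f, pts in enumerate(points_by_frame)]


def _partition(tracks):
    return sorted(
        tuple((int(f), round(float(x), 6), round(float(y), 6))
              for f, x, y in zip(t.frames, t.x, t.y))
        for t in tracks
    )


def _oracle_link(dets_by_frame, max_jump):
    """Frame-pair assignment maximising link count, then minimising total
    distance, by exhaustive enumeration (tiny instances only)."""
    tracks = []
    active = []  # (key points list, last det)
    for dets in dets_by_frame:
        prev = [t[-1] for t in active]
        best = None
        for r in range(min(len(prev), len(dets)), -1, -1):
            feasible = []
            for pi in itertools.combinations(range(len(prev)), r):
                for cj in itertools.permutations(range(len(dets)), r):
                    pairs = list(zip(pi, cj))
                    d = [np.hypot(prev[a].x - dets[b].x, prev[a].y - dets[b].y)
                         for a, b in pairs]
                    if all(v <= max_jump for v in d):
                        feasible.append((sum(d), pairs))
            if feasible:
                best = min(feasible, key=lambda t: t[0])[1]
                break
        best = best or []
        matched_prev = {a for a, _ in best}
        matched_cur = {b for _, b in best}
        new_active = []
        for a, b in best:
            active[a].append(dets[b])
            new_active.append(active[a])
        for i, t in enumerate(active):
            if i not in matched_prev:
                tracks.append(t)
        for j, d in enumerate(dets):
            if j not in matched_cur:
                new_active.append([d])
        active = new_active
    tracks.extend(active)
    return sorted(
        tuple((d.frame_index, round(d.x, 6), round(d.y, 6)) for d in t)
        for t in tracks
    )


class TestLinking:
    def test_stationary_blob_yields_single_track(self):
        dets = _dets([[(50.0, 60.0)]] * 10)
        tracks = link_detections(dets, max_jump=20)
        assert len(tracks) == 1 and len(tracks[0]) == 10

    def test_two_distant_movers_no_identity_swap(self):
        pts = [[(10.0 + 2 * f, 50.0), (510.0 + 2 * f, 50.0)] for f in range(10)]
        tracks = link_detections(_dets(pts), max_jump=20)
        assert len(tracks) == 2
        for t in tracks:
            assert len(t) == 10
            assert np.all(np.abs(np.diff(t.x) - 2.0) < 1e-9)

    def test_jump_above_cutoff_splits_track(self):
        dets = _dets([[(10.0, 10.0)], [(60.0, 10.0)]])
        tracks = link_detections(dets, max_jump=20)
        assert len(tracks) == 2

    def test_greedy_matches_exhaustive_oracle_when_well_separated(self):
        # <= 3 objects over 5 frames; starts >= 150 px apart, steps <= 5 px,
        # so inter-object spacing always exceeds twice the maximum step
        rng = np.random.default_rng(23)
        for _ in range(40):
            n_obj = rng.integers(1, 4)
            starts = [(200.0 * k + rng.uniform(0, 40), rng.uniform(0, 40))
                      for k in range(n_obj)]
            # each object may disappear partway (track termination)
            lifespan = [rng.integers(2, 6) for _ in range(n_obj)]
            pts_by_frame = []
            pos = list(starts)
            for f in range(5):
                pts = []
                for k in range(n_obj):
                    if f < lifespan[k]:
                        if f > 0:
                            pos[k] = (pos[k][0] + rng.uniform(-5, 5),
                                      pos[k][1] + rng.uniform(-5, 5))
                        pts.append(pos[k])
                pts_by_frame.append(pts)
            dets = _dets(pts_by_frame)
            got = _partition(link_detections(dets, max_jump=10.0))
            want = _oracle_link(dets, max_jump=10.0)
            assert got == want

    def test_unordered_frames_error(self):
        dets = [[Detection(3, 1.0, 1.0, 5)], [Detection(1, 2.0, 2.0, 5)]]
        with pytest.raises(ValueError):
            link_detections(dets)

    def test_conservation_and_jump_bound_on_fixture(self, rendered, tracked):
        """Every detection belongs to exactly one track and no link exceeds
        the cutoff."""
        dets = tracker.detect_stack(rendered["frames"], seed=5)
        total = sum(len(d) for d in dets)
        tracks = tracked["tracks"]
        assert total == sum(len(t) for t in tracks)
        for t in tracks:
            if len(t) > 1:
                assert np.all(np.hypot(np.diff(t.x), np.diff(t.y)) <= 20.0 + 1e-9)

    def test_bgmodel_and_fixed_threshold_agree_on_landed_only_fixture(self, small_arena):
        """With only opaque landed blobs on a uniform background the two
        foreground methods find identical blobs."""
        import heatseek as hs

        params = hs.BehaviorParams(n_mosquitoes=6, arrival_rate_zone1=0.05,
                                   arrival_rate_zone2=0.05, stationary_fraction=0.0)
        truth = hs.simulate_ground_truth(small_arena, params, seed=9)
        landed_only = truth.table[truth.table["state"] != "flying"].reset_index(drop=True)
        truth_l = hs.GroundTruth(small_arena, landed_only)
        frames = hs.render_frames(truth_l, small_arena, render_seed=10, noise_sd=0.0)
        d_bg = tracker.detect_stack(frames, method="bgmodel", seed=1)
        d_fx = tracker.detect_stack(frames, method="fixed", level=128)
        assert d_bg == d_fx


def test_centroids_match_ground_truth_on_noise_free_fixture(small_arena):
    """Noise-free rendering round-trip: recovered centroids within 0.5 px RMS."""
    import heatseek as hs

    params = hs.BehaviorParams(n_mosquitoes=1, arrival_rate_zone1=1.0,
                               arrival_rate_zone2=1.0, bout_mean_s=1e6,
                               stationary_fraction=0.0)
    truth = hs.simulate_ground_truth(small_arena, params, seed=2)
    seek = truth.table[truth.table["state"] == "landed_seeking"]
    assert len(seek) > 100
    frames = hs.render_frames(truth, small_arena, render_seed=1, noise_sd=0.0)
    err = []
    for i in range(frames.n_frames):
        dets = detect_blobs(threshold_mask(frames.frames[i], 128), frame_index=i)
        row = seek[seek["frame"] == i]
        if len(row) == 1 and len(dets) == 1:
            err.append((dets[0].x - row["x_px"].iloc[0]) ** 2
                       + (dets[0].y - row["y_px"].iloc[0]) ** 2)
    assert len(err) > 100
    assert np.sqrt(np.mean(err)) <= 0.5
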