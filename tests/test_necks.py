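"""Closest border pairs, intensity-weighted neck paths, stubby classification."""

import heapq
import math
from itertools import product

import numpy as np
import pytest

import spinemorph as sm
from spinemorph.necks import NeckPath, border_voxels, trace_neck


def brute_force_closest_pair(head_mask, dend_mask, spacing):
    dx, dy, dz = spacing
    sp = np.array([dz, dy, dx])
    hb = border_voxels(head_mask)
    db = border_voxels(dend_mask)
    best = None
    for h in map(tuple, hb):
        for d in map(tuple, db):
            dist = float(np.linalg.norm((np.asarray(h) - np.asarray(d)) * sp))
            key = (dist, h, d)
            if best is None or key < best:
                best = key
    return best[1], best[2], best[0]


def dijkstra_oracle(data, spacing_zyx, start, goal, blocked):
    """Plain-dict exhaustive lowest-cost-path search (the oracle)."""
    imax, imin = float(data.max()), float(data.min())
    span = imax - imin
    steps = [s for s in product((-1, 0, 1), repeat=3) if s != (0, 0, 0)]
    dist = {start: 0.0}
    prev = {}
    heap = [(0.0, start)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        for s in steps:
            v = tuple(a + b for a, b in zip(u, s))
            if not all(0 <= v[i] < data.shape[i] for i in range(3)):
                continue
            if blocked[v]:
                continue
            w = 1.0 if span == 0 else 1.0 + (imax - data[v]) / span
            nd = d + float(np.linalg.norm(np.asarray(s) * spacing_zyx)) * w
            if nd < dist.get(v, np.inf) - 1e-15:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    if goal not in dist:
        return None, np.inf
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    return path[::-1], dist[goal]


class TestClosestPair:
    def test_sphere_above_cylinder_distance(self, mixed_phantom):
        stack, truth = mixed_phantom
        state = sm.build_state(stack, truth.dendrite_model, sm.RunConfig())
        sm.detect_stage(state)
        sm.segment_stage(state)
        # every necked spine's head sits ~1.0 µm off the dendrite surface
        necked = [
            h for h in state.heads
            if sm.classify_stubby(h.mask(stack.shape), state.volume.mask) == "necked"
        ]
        assert len(necked) == 5
        for head in necked:
            _, _, dist = sm.closest_border_pair(
                head.mask(stack.shape), state.volume.mask, stack.spacing
            )
            assert dist == pytest.approx(1.0, abs=0.25)

    def test_adjacent_head_distance_within_one_step(self):
        head = np.zeros((6, 6, 6), bool)
        dend = np.zeros((6, 6, 6), bool)
        dend[:, :, 0:2] = True
        head[2:4, 2:4, 2:4] = True  # face-adjacent to the dendrite at x=2
        hv, dv, dist = sm.closest_border_pair(head, dend, (0.1, 0.1, 0.1))
        assert dist <= 0.1 + 1e-9

    def test_matches_exhaustive_pair_scan(self, rng):
        spacing = (0.07, 0.11, 0.23)
        for _ in range(6):
            head = np.zeros((10, 10, 10), bool)
            dend = np.zeros((10, 10, 10), bool)
            c = rng.integers(5, 9, 3)
            head[c[0] - 1:c[0] + 1, c[1] - 1:c[1] + 1, c[2] - 1:c[2] + 1] = True
            dend[0:2, :, :] = True
            got = sm.closest_border_pair(head, dend, spacing)
            want = brute_force_closest_pair(head, dend, spacing)
            assert got[2] == pytest.approx(want[2])
            assert (got[0], got[1]) == (want[0], want[1])


class TestTrace:
    def test_straight_bright_neck_length(self, mixed_phantom):
        stack, truth = mixed_phantom
        state = sm.build_state(stack, truth.dendrite_model, sm.RunConfig())
        sm.detect_stage(state)
        sm.segment_stage(state)
        sm.trace_stage(state)
        diag = float(np.linalg.norm(stack.spacing_zyx))
        for lab, path in state.neck_paths.items():
            assert path.mode == "traced"
            assert abs(path.length - 1.0) <= diag

    def test_bright_corridor_beats_dark_shortcut(self):
        """An L-shaped bright corridor is preferred to the dark diagonal."""
        data = np.full((3, 9, 9), 1.0)
        data[1, 1, 1:8] = 100.0  # horizontal arm
        data[1, 1:8, 7] = 100.0  # vertical arm
        stack = sm.ImageStack(data, (0.1, 0.1, 0.1))
        head = np.zeros(data.shape, bool)
        head[1, 1, 0] = True
        dend = np.zeros(data.shape, bool)
        dend[1, 8, 7] = True
        path = trace_neck(stack, (1, 1, 0), (1, 8, 7), head, dend)
        vox = np.array(path.voxels)
        # path hugs the corridor: all intermediate voxels bright
        inner = vox[1:]
        assert (data[tuple(inner.T)] == 100.0).all()

    def test_matches_exhaustive_path_oracle(self, rng):
        spacing = (0.1, 0.1, 0.2)
        sp = np.array([0.2, 0.1, 0.1])
        for _ in range(5):
            data = rng.uniform(0, 255, (7, 7, 7))
            head = np.zeros(data.shape, bool)
            head[0, 0, 0] = True
            dend = np.zeros(data.shape, bool)
            dend[6, 6, 6] = True
            stack = sm.ImageStack(data, spacing)
            got = trace_neck(stack, (0, 0, 0), (6, 6, 6), head, dend)
            blocked = np.zeros(data.shape, bool)
            want_path, want_cost = dijkstra_oracle(
                data, sp, (0, 0, 0), (6, 6, 6), blocked
            )
            assert got.voxels == want_path[:-1]

    def test_dark_corridor_falls_back_to_straight_line(self, caplog):
        data = np.zeros((3, 5, 5))
        stack = sm.ImageStack(data, (0.1, 0.1, 0.1))
        head = np.zeros(data.shape, bool)
        dend = np.zeros(data.shape, bool)
        head[1, 0, 0] = True
        dend[1, 4, 4] = True
        # wall of blocked voxels between them
        head[:, 2, :] = True
        with caplog.at_level("WARNING", logger="spinemorph.necks"):
            path = trace_neck(stack, (1, 0, 0), (1, 4, 4), head, dend)
        assert path.mode == "straight_line"
        assert path.length == pytest.approx(np.hypot(0.4, 0.4))
        assert "fallback" in caplog.text

    def test_traced_cost_not_worse_than_straight_line(self, mixed_phantom):
        """Optimality witness: each traced path's cost <= straight voxel line."""
        stack, truth = mixed_phantom
        state = sm.build_state(stack, truth.dendrite_model, sm.RunConfig())
        sm.detect_stage(state)
        sm.segment_stage(state)
        sm.trace_stage(state)
        for lab, path in state.neck_paths.items():
            head = next(h for h in state.heads if h.label == lab)
            hv, dv, gap = sm.closest_border_pair(
                head.mask(stack.shape), state.volume.mask, stack.spacing
            )
            diag = float(np.linalg.norm(stack.spacing_zyx))
            assert path.length >= gap - diag
            # no neck voxel inside head or dendrite
            hmask = head.mask(stack.shape)
            for v in path.voxels[1:]:
                assert not state.volume.mask[v]
                assert not hmask[v]


class TestStraightLine:
    def test_by_construction_distance(self):
        dend = np.zeros((9, 9, 9), bool)
        dend[:, :, 0:2] = True
        head_vox = np.array([[4, 4, 6]])
        head = sm.SpineHead(1, head_vox, [], (0.1, 0.1, 0.1))
        got = sm.straight_line_length(head, dend, (0.1, 0.1, 0.1))
        # centroid x = 0.65; nearest border voxel center x = 0.15, same y/z
        assert got == pytest.approx(0.5)

    def test_equals_brute_force_min_over_surface(self, rng):
        spacing = (0.08, 0.13, 0.21)
        sp = np.array([0.21, 0.13, 0.08])
        dend = np.zeros((8, 8, 8), bool)
        dend[0:3, 2:6, 2:6] = True
        head_vox = rng.integers(4, 8, (6, 3))
        head = sm.SpineHead(1, head_vox, [], spacing)
        got = sm.straight_line_length(head, dend, spacing)
        cx, cy, cz = head.centroid
        cen = np.array([cz, cy, cx])
        want = min(
            float(np.linalg.norm((np.asarray(b) + 0.5) * sp - cen))
            for b in border_voxels(dend)
        )
        assert got == pytest.approx(want)


class TestClassify:
    def test_face_adjacent_head_is_stubby(self):
        head = np.zeros((6, 6, 6), bool)
        dend = np.zeros((6, 6, 6), bool)
        dend[:, :, 0:2] = True
        head[2:4, 2:4, 2:4] = True
        assert sm.classify_stubby(head, dend) == "stubby"

    def test_separated_head_is_necked(self):
        head = np.zeros((10, 10, 10), bool)
        dend = np.zeros((10, 10, 10), bool)
        dend[:, :, 0:2] = True
        head[4:6, 4:6, 7:9] = True  # 0.5 µm gap at 0.1 spacing
        assert sm.classify_stubby(head, dend) == "necked"

    def test_phantom_mixture_classified_perfectly(self, mixed_phantom):
        stack, truth = mixed_phantom
        state = sm.build_state(stack, truth.dendrite_model, sm.RunConfig())
        sm.detect_stage(state)
        sm.segment_stage(state)
        sm.trace_stage(state)
        sm.measure_stage(state)
        res = sm.evaluate_detection(
            [r.head_centroid for r in state.records], truth, 0.5
        )
        assert res["recall"] == 1.0 and res["precision"] == 1.0
        by_id = {r.spine_id: r for r in state.records}
        correct = sum(
            by_id[pi + 1].spine_type == truth.spines[ti].kind
            for pi, ti, _ in res["matches"]
        )
        assert correct == 8


class TestRetrace:
    @pytest.fixture
    def traced_state(self, mixed_phantom):
        stack, truth = mixed_phantom
        state = sm.build_state(stack, truth.dendrite_model, sm.RunConfig())
        sm.detect_stage(state)
        sm.segment_stage(state)
        sm.trace_stage(state)
        return state

    def test_same_start_is_idempotent(self, traced_state):
        state = traced_state
        lab, path = next(iter(state.neck_paths.items()))
        head = next(h for h in state.heads if h.label == lab)
        again = sm.retrace_neck(
            state.image, head.mask(state.image.shape), path.voxels[0],
            state.volume.mask, label=lab,
        )
        assert again.voxels == path.voxels

    def test_far_side_start_gives_longer_valid_path(self, traced_state):
        state = traced_state
        lab, path = next(iter(state.neck_paths.items()))
        head = next(h for h in state.heads if h.label == lab)
        hmask = head.mask(state.image.shape)
        hb = border_voxels(hmask)
        start = np.asarray(path.voxels[0])
        far = tuple(int(v) for v in hb[np.argmax(np.linalg.norm(hb - start, axis=1))])
        new = sm.retrace_neck(state.image, hmask, far, state.volume.mask, label=lab)
        assert new.length > path.length
        assert new.voxels[0] == far
        for v in new.voxels:
            assert not state.volume.mask[v]

    def test_off_border_start_rejected(self, traced_state):
        state = traced_state
        head = state.heads[0]
        with pytest.raises(ValueError, match="border"):
            sm.retrace_neck(
                state.image, head.mask(state.image.shape), (0, 0, 0),
                state.volume.mask,
            )
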