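"""Codec: channel encoding, DFS line extraction, orientation, round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pigtrace import codec, sim
from pigtrace.codec import (CH_BODY_LINE, CH_LEFT_EAR, CH_LEFT_EAR_LINE,
                            CH_RIGHT_EAR, CH_RIGHT_EAR_LINE, CH_SHOULDER,
                            CH_TAIL, ChannelStack)
from pigtrace.pose import PigPose


# -- independent oracle: flood fill + quadratic diameter search -------------

def oracle_extract(img, min_pixels):
    img = np.asarray(img) > 0
    h, w = img.shape
    seen = np.zeros_like(img, dtype=bool)
    pairs = []
    for y in range(h):
        for x in range(w):
            if not img[y, x] or seen[y, x]:
                continue
            stack, comp = [(y, x)], []
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                comp.append((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < h and 0 <= nx < w and img[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            if len(comp) < min_pixels:
                continue
            best, best_pair = -1, None
            for i in range(len(comp)):
                for j in range(i + 1, len(comp)):
                    d = ((comp[i][0] - comp[j][0]) ** 2
                         + (comp[i][1] - comp[j][1]) ** 2)
                    pair = tuple(sorted((comp[i], comp[j])))
                    if d > best or (d == best and pair < best_pair):
                        best, best_pair = d, pair
            if best_pair is None:
                best_pair = (comp[0], comp[0])
            (y0, x0), (y1, x1) = best_pair
            pairs.append(((float(x0), float(y0)), (float(x1), float(y1))))
    return sorted(pairs)


def test_encode_empty_is_all_zero():
    stack = codec.encode([], 64, 64)
    assert stack.channels.shape == (7, 64, 64)
    assert stack.channels.sum() == 0


def test_encode_vertical_body_line_is_connected():
    from scipy import ndimage
    p = PigPose(shoulder=(100, 100), tail=(100, 190))
    stack = codec.encode([p], 400, 640)
    labels, n = ndimage.label(stack[CH_BODY_LINE],
                              structure=np.ones((3, 3), int))
    assert n == 1
    ys = np.nonzero(stack[CH_BODY_LINE][:, 100])[0]
    assert ys.min() <= 100 and ys.max() >= 190


def test_encode_without_ears_leaves_ear_channels_empty():
    p = PigPose(shoulder=(50, 50), tail=(100, 100))
    stack = codec.encode([p], 200, 200)
    for ch in (CH_LEFT_EAR, CH_RIGHT_EAR, CH_LEFT_EAR_LINE, CH_RIGHT_EAR_LINE):
        assert stack[ch].sum() == 0
    assert stack[CH_SHOULDER].sum() > 0 and stack[CH_TAIL].sum() > 0


def test_encode_rejects_out_of_bounds_pose():
    p = PigPose(shoulder=(50, 50), tail=(300, 50), id=9)
    with pytest.raises(ValueError, match="id=9"):
        codec.encode([p], 100, 100)


def test_extract_lines_empty_image():
    assert codec.extract_lines(np.zeros((32, 32))) == []


def test_extract_lines_two_disjoint_segments():
    from skimage.draw import line
    img = np.zeros((200, 200), dtype=np.uint8)
    segs = [((10, 20), (90, 20)), ((150, 100), (150, 160))]  # (y,x) ends
    for (y0, x0), (y1, x1) in segs:
        rr, cc = line(y0, x0, y1, x1)
        img[rr, cc] = 1
    pairs = codec.extract_lines(img)
    assert len(pairs) == 2
    found = sorted(pairs)
    true = sorted([((20.0, 10.0), (20.0, 90.0)), ((100.0, 150.0), (160.0, 150.0))])
    for (p0, p1), (t0, t1) in zip(found, true):
        assert np.hypot(*(np.subtract(p0, t0))) <= 2
        assert np.hypot(*(np.subtract(p1, t1))) <= 2


def test_min_component_pixels_discards_specks():
    img = np.zeros((40, 40), dtype=np.uint8)
    img[5, 5] = 1  # single-pixel speck
    img[20, 10:30] = 1  # 20-px line
    pairs = codec.extract_lines(img, min_component_pixels=10)
    assert len(pairs) == 1


@given(st.integers(0, 10_000))
def test_extract_lines_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    img = np.zeros((48, 48), dtype=np.uint8)
    from skimage.draw import line
    for _ in range(rng.integers(1, 4)):
        y0, x0, y1, x1 = rng.integers(0, 48, size=4)
        rr, cc = line(y0, x0, y1, x1)
        img[rr, cc] = 1
    got = sorted(codec.extract_lines(img, min_component_pixels=3))
    assert got == oracle_extract(img, min_pixels=3)


def test_orient_resolves_shoulder_from_shoulder_channel():
    p = PigPose(shoulder=(40, 60), tail=(140, 60),
                left_ear=(30, 50), right_ear=(30, 70))
    stack = codec.encode([p], 200, 200)
    poses = codec.decode(stack)
    assert len(poses) == 1
    q = poses[0]
    assert not q.ambiguous
    assert np.hypot(q.shoulder[0] - 40, q.shoulder[1] - 60) <= codec.DEFAULT_MARKER_RADIUS
    assert np.hypot(q.tail[0] - 140, q.tail[1] - 60) <= codec.DEFAULT_MARKER_RADIUS
    assert q.left_ear is not None and q.right_ear is not None


def test_orient_resolves_from_ear_evidence_when_shoulder_channel_empty():
    p = PigPose(shoulder=(40, 60), tail=(140, 60),
                left_ear=(30, 50), right_ear=(30, 70))
    stack = codec.encode([p], 200, 200)
    stack.channels[CH_SHOULDER] = 0
    poses = codec.decode(stack)
    assert len(poses) == 1
    q = poses[0]
    assert not q.ambiguous
    assert abs(q.shoulder[0] - 40) <= codec.DEFAULT_MARKER_RADIUS + 1


def test_orient_flags_symmetric_fixture_ambiguous():
    # bare line: no shoulder disc, no ears -> no orientation evidence
    from skimage.draw import line
    stack = np.zeros((7, 100, 100), dtype=np.uint8)
    rr, cc = line(50, 20, 50, 80)
    stack[CH_BODY_LINE][rr, cc] = 1
    poses = codec.decode(ChannelStack(stack))
    assert len(poses) == 1
    assert poses[0].ambiguous
    assert poses[0].orientation is None


def test_decode_thresholding():
    assert codec.decode(ChannelStack(np.full((7, 64, 64), 0.4))) == []
    # all-0.6 stack: one giant component; must decode without crashing
    poses = codec.decode(ChannelStack(np.full((7, 64, 64), 0.6)))
    assert len(poses) <= 1


def test_decode_never_returns_more_poses_than_line_components():
    cfg = sim.PenConfig(n_pigs=6, seed=2)
    truth = sim.simulate_pen(cfg, 5)
    from scipy import ndimage
    for frame in truth.poses:
        stack = codec.encode(frame, cfg.height, cfg.width)
        _, n = ndimage.label(stack[CH_BODY_LINE], structure=np.ones((3, 3), int))
        assert len(codec.decode(stack)) <= n


def _pairwise_separated(frame, min_sep):
    from shapely.geometry import LineString
    segs = [LineString([p.shoulder, p.tail]) for p in frame]
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segs[i].distance(segs[j]) <= min_sep:
                return False
    return True


def test_roundtrip_recovers_separated_pigs():
    cfg = sim.PenConfig(n_pigs=5, seed=13)
    truth = sim.simulate_pen(cfg, 30)
    min_sep = 2 * codec.DEFAULT_MARKER_RADIUS + cfg.body_length / 4
    checked = 0
    for frame in truth.poses:
        if not _pairwise_separated(frame, min_sep):
            continue
        checked += 1
        decoded = codec.decode(codec.encode(frame, cfg.height, cfg.width))
        assert len(decoded) == len(frame)
        for q in decoded:
            err = min(np.hypot(q.shoulder[0] - p.shoulder[0],
                               q.shoulder[1] - p.shoulder[1]) for p in frame)
            assert err <= codec.DEFAULT_MARKER_RADIUS
            assert not q.ambiguous
    assert checked > 0
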