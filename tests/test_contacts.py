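"""Contact regions, typed events, episodes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pigtrace import contacts as c
from pigtrace.pose import PigPose

from conftest import oracle_contacts, table_rows


def P(id, shoulder, tail, frame=0):
    return PigPose(shoulder=shoulder, tail=tail, frame=frame, id=id)


# -- radius -----------------------------------------------------------------

def test_radius_equal_lengths_is_length_over_alpha():
    poses = [P(0, (0, 0), (90, 0)), P(1, (0, 50), (90, 50))]
    assert c.region_radius(poses, alpha=3) == pytest.approx(30.0)


def test_radius_mixed_lengths():
    poses = [P(0, (0, 0), (60, 0)), P(1, (0, 50), (120, 50))]
    assert c.region_radius(poses, alpha=3) == pytest.approx(30.0)


def test_radius_345_triangle():
    assert c.region_radius([P(0, (0, 0), (3, 4))], alpha=1) == pytest.approx(5.0)


def test_radius_empty_frame_errors():
    with pytest.raises(ValueError):
        c.region_radius([], alpha=3)


@given(st.lists(st.tuples(st.floats(0, 500), st.floats(0, 500),
                          st.floats(0, 500), st.floats(0, 500)),
                min_size=1, max_size=8),
       st.floats(0.5, 10))
def test_radius_matches_mean_length_oracle(coords, alpha):
    poses = [P(i, (sx, sy), (tx, ty))
             for i, (sx, sy, tx, ty) in enumerate(coords)]
    expect = np.mean([p.body_length for p in poses]) / alpha
    assert c.region_radius(poses, alpha) == pytest.approx(expect, rel=1e-12)


# -- regions ----------------------------------------------------------------

def test_head_center_defaults_to_shoulder():
    rs = c.make_regions([P(0, (100, 100), (100, 190)),
                         P(1, (300, 100), (300, 190))], alpha=3)
    assert np.allclose(rs.head_centers[0], (100, 100))
    assert np.allclose(rs.tail_centers[0], (100, 190))
    assert rs.radius == pytest.approx(30.0)


def test_head_center_offset_along_orientation():
    rs = c.make_regions([P(0, (100, 100), (100, 190)),
                         P(1, (300, 100), (300, 190))],
                        alpha=3, head_offset_frac=1.0)
    # orientation points from tail (y=190) to shoulder (y=100): -y
    assert np.allclose(rs.head_centers[0], (100, 70))


def test_degenerate_poses_excluded():
    rs = c.make_regions([P(0, (5, 5), (5, 5))], alpha=3)
    assert len(rs) == 0
    assert c.detect_contacts(rs) == []


# -- detection --------------------------------------------------------------

def two_pig_regions(head_dist, r=30.0):
    return c.RegionSet(frame=0, ids=[1, 2],
                       head_centers=np.array([[0., 0.], [head_dist, 0.]]),
                       tail_centers=np.array([[0., 500.], [head_dist, 500.]]),
                       radius=r)


def test_head_head_inside_threshold():
    events = c.detect_contacts(two_pig_regions(50.0))
    assert [(e.type, e.id_a, e.id_b) for e in events] == [("head-head", 1, 2)]


def test_head_head_boundary_inclusive_and_exclusive():
    assert len(c.detect_contacts(two_pig_regions(60.0))) == 1
    assert len(c.detect_contacts(two_pig_regions(61.0))) == 0


def test_single_pig_no_contacts():
    rs = c.RegionSet(frame=0, ids=[1], head_centers=np.zeros((1, 2)),
                     tail_centers=np.ones((1, 2)) * 100, radius=30)
    assert c.detect_contacts(rs) == []


def test_head_tail_role_tags_follow_geometry():
    # pig 2's head sits on pig 1's tail
    rs = c.RegionSet(frame=3, ids=[1, 2],
                     head_centers=np.array([[0., 0.], [10., 200.]]),
                     tail_centers=np.array([[0., 200.], [300., 300.]]),
                     radius=20.0)
    events = c.detect_contacts(rs)
    assert len(events) == 1
    e = events[0]
    assert (e.type, e.id_a, e.id_b, e.head_id, e.tail_id) == \
        ("head-tail", 1, 2, 2, 1)


def test_symmetry_under_pig_order():
    def mk(order):
        ids = [1, 2] if order else [2, 1]
        heads = np.array([[0., 0.], [50., 0.]])
        tails = np.array([[0., 40.], [50., 40.]])
        if not order:
            heads, tails = heads[::-1].copy(), tails[::-1].copy()
        return c.RegionSet(frame=0, ids=ids, head_centers=heads,
                           tail_centers=tails, radius=30.0)
    rows_a = sorted((e.type, e.id_a, e.id_b, e.head_id, e.tail_id)
                    for e in c.detect_contacts(mk(True)))
    rows_b = sorted((e.type, e.id_a, e.id_b, e.head_id, e.tail_id)
                    for e in c.detect_contacts(mk(False)))
    assert rows_a == rows_b


def random_frame(rng, n=6, frame=0):
    poses = []
    for i in range(n):
        s = rng.uniform(0, 400, size=2)
        ang = rng.uniform(0, 2 * np.pi)
        L = rng.uniform(40, 120)
        t = s + L * np.array([np.cos(ang), np.sin(ang)])
        poses.append(P(i, tuple(s), tuple(t), frame=frame))
    return poses


def test_detect_equals_bruteforce_on_random_frames():
    rng = np.random.default_rng(123)
    for k in range(200):
        poses = random_frame(rng, n=int(rng.integers(1, 8)), frame=k)
        got = table_rows(c.ContactTable(c.frame_contacts(poses)))
        assert got == oracle_contacts([poses])


def test_alpha_monotonicity_never_adds_events():
    rng = np.random.default_rng(7)
    for k in range(50):
        poses = random_frame(rng, n=5, frame=k)
        small = set(table_rows(c.ContactTable(c.frame_contacts(poses, alpha=6.0))))
        large = set(table_rows(c.ContactTable(c.frame_contacts(poses, alpha=3.0))))
        assert small <= large


# -- table / episodes -------------------------------------------------------

def make_table(frames, typ=c.HEAD_HEAD):
    events = [c.ContactEvent(f, 1, 2, typ,
                             head_id=1 if typ == c.HEAD_TAIL else None,
                             tail_id=2 if typ == c.HEAD_TAIL else None)
              for f in frames]
    return c.ContactTable(sorted(events, key=c.ContactEvent.sort_key))


def test_episode_merge_semantics_gap_zero():
    eps = make_table([10, 11, 12, 20]).episodes(gap_tolerance=0)
    spans = [(e.start_frame, e.end_frame, e.n_frames) for e in eps]
    assert spans == [(10, 12, 3), (20, 20, 1)]


def test_episode_merge_bridges_gaps_within_tolerance():
    eps = make_table([10, 12, 14, 25]).episodes(gap_tolerance=2)
    spans = [(e.start_frame, e.end_frame) for e in eps]
    assert spans == [(10, 14), (25, 25)]


def test_episode_conservation_at_zero_gap():
    rng = np.random.default_rng(5)
    frames = sorted(rng.choice(200, size=60, replace=False))
    table = make_table(frames)
    eps = table.episodes(gap_tolerance=0)
    assert sum(e.n_frames for e in eps) == len(table)


def test_build_contact_table_from_tracks(scripted_truth):
    from pigtrace import tracker, sim
    cfg, script, truth = scripted_truth
    dets = sim.corrupt_detections(truth, sim.NoiseConfig())
    tracks = tracker.track_sequence(dets, tracker.TrackerConfig(n_pigs=2))
    table = c.build_contact_table(tracks)
    df = table.to_frame()
    hh = df[(df.type == "head-head") & (df.frame >= 20) & (df.frame <= 30)]
    assert len(hh) >= 1  # staged contact recovered end-to-end


def test_empty_tracks_empty_table():
    assert len(c.build_contact_table([])) == 0
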