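import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from pigtrace import sim


# ---------------------------------------------------------------------------
# independent brute-force contact oracle (kept free of pigtrace.contacts
# internals: plain loops and arithmetic only)

def oracle_contacts(per_frame_poses, alpha=3.0, head_offset_frac=0.0):
    """All-pairs circle-intersection contact rows, computed from scratch."""
    rows = []
    for poses in per_frame_poses:
        poses = [p for p in poses if p.id is not None and p.body_length > 0]
        if not poses:
            continue
        r = sum(math.dist(p.shoulder, p.tail) for p in poses) / (alpha * len(poses))
        heads, tails = {}, {}
        for p in poses:
            ux = (p.shoulder[0] - p.tail[0]) / math.dist(p.shoulder, p.tail)
            uy = (p.shoulder[1] - p.tail[1]) / math.dist(p.shoulder, p.tail)
            heads[p.id] = (p.shoulder[0] + head_offset_frac * r * ux,
                           p.shoulder[1] + head_offset_frac * r * uy)
            tails[p.id] = p.tail
        ids = sorted(heads)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                f = poses[0].frame
                if math.dist(heads[a], heads[b]) <= 2 * r:
                    rows.append((f, a, b, "head-head", None, None))
                if math.dist(heads[a], tails[b]) <= 2 * r:
                    rows.append((f, a, b, "head-tail", a, b))
                if math.dist(heads[b], tails[a]) <= 2 * r:
                    rows.append((f, a, b, "head-tail", b, a))
    return sorted(rows)


def table_rows(table):
    return sorted((e.frame, e.id_a, e.id_b, e.type, e.head_id, e.tail_id)
                  for e in table.events)


@pytest.fixture(scope="session")
def clean_run_5pigs():
    """Clean 5-pig, 200-frame simulation with noise-free detections."""
    cfg = sim.PenConfig(n_pigs=5, seed=11)
    truth = sim.simulate_pen(cfg, 200)
    dets = sim.corrupt_detections(truth, sim.NoiseConfig())
    return cfg, truth, dets


@pytest.fixture(scope="session")
def scripted_truth():
    """2 pigs with a staged head-head approach in frames 20-30."""
    cfg = sim.PenConfig(n_pigs=2, seed=7)
    script = [sim.ApproachEvent("head-head", 0, 1, 20, 30)]
    return cfg, script, sim.simulate_pen(cfg, 60, script)
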