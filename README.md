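# pigtrace

Automated quantification of social contacts between group-housed pigs
from overhead video, using keypoint-based tracking-by-detection.

Manual scoring of social encounters (the standard in behavioural
studies of pig welfare, hierarchy formation, and agonistic behaviour
such as tail biting) is slow and observer-biased.  `pigtrace`
implements the full automated alternative for a pen with a **known
number of animals**: per-frame body-part detections (shoulder, tail,
left/right ear) are linked into identity-stable trajectories with a
Kalman filter, head–head and head–tail contacts are identified from
per-frame proximity regions, and the resulting contact table is
aggregated into weighted social networks ready for social-network
analysis.

The package is aimed at precision-livestock-farming and behavioural
researchers who have (or simulate) keypoint detections and want
reproducible contact tables and networks, plus the standard evaluation
metrics to validate a detector/tracker combination.

## Core quantities

With shoulder and tail coordinates `s_i`, `t_i` of the `N` animals in a
frame, head and tail regions are circles of radius

    r = (1 / (α·N)) · Σ_i ‖s_i − t_i‖        (default α = 3)

centred at each animal's shoulder and tail keypoint.  Two animals are
in **head–head** contact when their head circles intersect
(`‖head_a − head_b‖ ≤ 2r`) and in **head–tail** contact when one head
circle intersects the other's tail circle (role-tagged).  The radius is
recomputed every frame, so regions scale with animal growth.

Detection quality is scored with circular detection regions (radius =
mean shoulder-to-ear distance per frame) via sensitivity, precision and
F1; tracking quality via Multiple Object Tracking Accuracy,

    MOTA = 1 − (FP_T + FN_T + IDSW) / N_CNN .

A built-in pen simulator generates seeded ground-truth trajectories,
staged contacts and detector-noise models (jitter, dropouts,
occlusions, spurious poses, shoulder–tail swaps), so the whole pipeline
is testable without farm video.  An optional module builds and trains
the reference 25-layer encoder–decoder keypoint CNN (pure numpy) at
desk scale.

## Worked example

```python
from pigtrace import sim, tracker, contacts, network, evalmetrics as ev

cfg = sim.PenConfig(n_pigs=4, seed=3)                      # 640x400 pen, 10 fps
script = [sim.ApproachEvent("head-head", 0, 1, 40, 55),
          sim.ApproachEvent("head-tail", 2, 3, 90, 110)]
truth = sim.simulate_pen(cfg, 150, script)
dets = sim.corrupt_detections(truth, sim.NoiseConfig(jitter_sigma=1.0,
                                                     fn_rate=0.02, seed=3))

tracks = tracker.track_sequence(dets, tracker.TrackerConfig(n_pigs=4))
table = contacts.build_contact_table(tracks, alpha=3.0)
print(table.to_frame().head(6).to_string(index=False))
print(f"{len(table)} contact rows, "
      f"{len(table.episodes(gap_tolerance=5))} episodes")

g = network.build_network(table, "all", node_ids=[t.id for t in tracks])
for a, b, d in g.edges(data=True):
    print(f"edge {a}-{b}: weight {d['weight']}")

first = tracks[0].frames[0]
res = ev.classify_tracking(
    ev.poses_to_point_frames(truth.poses[first:]),
    ev.tracks_to_point_frames(tracks, truth.n_frames, first_frame=first),
    loc_thresholds=[ev.detection_region_radius(f) for f in truth.poses[first:]])
print(f"MOTA = {res.mota:.3f}  (FP={res.fp}, FN={res.fn}, IDSW={res.idsw}, "
      f"N={res.n_points})")
```

Output:

```
 frame  id_a  id_b      type  head_id  tail_id
     3     3     4 head-tail      4.0      3.0
     4     3     4 head-tail      4.0      3.0
     6     1     2 head-head      NaN      NaN
     7     1     2 head-head      NaN      NaN
     8     1     2 head-head      NaN      NaN
     8     1     4 head-head      NaN      NaN
...
478 contact rows, 59 episodes
edge 1-2: weight 92
edge 1-4: weight 75
edge 1-3: weight 81
edge 2-3: weight 91
edge 2-4: weight 35
edge 3-4: weight 104
MOTA = 0.998  (FP=0, FN=0, IDSW=1, N=600)
```

The contact table lists one row per contacting pair per frame (for
head–tail rows, `head_id` says whose head touched whose tail); edge
weights count contact frames per pair; the MOTA line shows that with
mild detector noise (2% dropouts), 600 evaluated animal-frames incur a
single identity switch and no localisation failures.

The same pipeline is scriptable from the shell:

```sh
pigtrace simulate --n-pigs 4 --n-frames 150 --seed 3 --out-dir run/
pigtrace track --detections run/detections.csv --n-pigs 4 --out run/tracks.csv
pigtrace contacts --tracks run/tracks.csv --out run/contacts.csv
pigtrace network --contacts run/contacts.csv --out run/net.graphml
pigtrace eval --truth run/truth_poses.csv --tracks run/tracks.csv --out run/metrics.json
```

## Layout

- `src/pigtrace/sim.py` — synthetic pen, trajectories, noise models
- `src/pigtrace/codec.py` — 7-channel keypoint image encode/decode
- `src/pigtrace/tracker.py` — Kalman filter + Hungarian association
- `src/pigtrace/contacts.py` — proximity regions, contact table, episodes
- `src/pigtrace/network.py` — weighted social networks, export, plots
- `src/pigtrace/evalmetrics.py` — detection scoring and MOTA
- `src/pigtrace/detector/` — optional numpy CNN (architecture,
  augmentation, preprocessing, toy training)
- `src/pigtrace/cli.py`, `pipeline.py`, `io.py` — orchestration and I/O

See `docs/methods.md` for the models, parameter choices and the
simulator's scope and limitations.
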