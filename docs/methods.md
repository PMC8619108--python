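# Methods

`pigtrace` implements a tracking-by-detection pipeline for quantifying
social contacts between a **known, fixed number of pigs** filmed from a
single overhead camera (640 x 400 px grayscale frames at 10 fps is the
reference geometry throughout).  This note documents the models, the
parameters that matter, the synthetic data used for validation, and the
numerical choices made where the design was genuinely open.

## Pose representation and the channel codec

Each animal is reduced to four keypoints — shoulder, tail, left ear,
right ear — with the body orientation defined as the unit vector from
tail to shoulder.  Annotations (and detector outputs) are stored as a
seven-channel binary image stack: four keypoint channels (filled discs,
default radius 4 px), the shoulder–tail line, and the two shoulder–ear
lines (rasterized segments, default width 3 px).  The channel order is
fixed as `[left ear, right ear, shoulder, tail, body line, left-ear
line, right-ear line]` and is configurable only through the module
constants; marker radius and line width were chosen so that discs of
neighbouring animals do not merge at typical inter-pig distances at
this resolution.

Decoding inverts the stack:

1. binarize real-valued channels at a threshold (default 0.5, the
   natural cut for sigmoid outputs);
2. label the body-line channel with **8-connected** components
   (8-connectivity tolerates diagonal rasterization); components with
   fewer than 10 set pixels are dropped as noise;
3. each component yields its **maximal-diameter pixel pair** as the
   line endpoints.  Squared distances are compared in exact integer
   arithmetic; ties resolve to the lexicographically smallest pair, so
   extraction is deterministic and matches a brute-force oracle
   exactly.  Large components are first reduced to their convex hull
   (the diameter of a finite point set is attained at hull vertices);
   degenerate collinear components fall back to brute force;
4. the endpoint nearer to a shoulder-channel blob (Euclidean distance
   transform lookup) is the shoulder; when the margin is below 1.5 px
   or the shoulder channel is empty, ear evidence (set pixels of the
   ear and ear-line channels within 30 px of each endpoint) breaks the
   tie.  With no decisive evidence the pose is kept but flagged
   *ambiguous*; ears are attached from the nearest ear-channel blob
   centroid within the same search radius.

Touching animals whose body lines merge into one component decode as a
single (usually ambiguous) pose.  Splitting merged components is out of
scope; this is exactly the occlusion regime in which any per-frame
detector fails, and the tracker is the layer designed to ride it out.

## Tracking

One Kalman filter per animal tracks the shoulder point with a
constant-velocity state (x, y, vx, vy), unit frame time.  At 10 fps
even brisk pig motion displaces keypoints by only a few pixels per
frame, so constant velocity with modest process noise (discrete
white-noise acceleration, intensity 1 px²/frame⁴ scaled by the
standard coupling matrix) is adequate.  Defaults: measurement noise
4 px², initial position variance 10 px², initial velocity variance
25 px² at zero initial velocity.  These values are this package's
choices; they are not claimed to reproduce any particular prior work's
initialization.

Detections are assigned to filter predictions by minimum total
Euclidean distance (Hungarian algorithm; a greedy nearest-first
variant is available by configuration).  Matches beyond a gate radius
are rejected; the default gate is the median shoulder-tail body length
of the initialization frame, which scales the gate with animal size.
Tracking starts at the first frame whose detection count equals the
known animal count, and identities 1..n are assigned in that frame's
detection order; there is no track birth or death.

A frame whose detection count differs from the expected count is
flagged **corrupted**: its detections are discarded and every filter
is updated with its own previous estimate as a surrogate measurement
under measurement noise inflated by a factor of 10.  This implements
"down-weight the input signal when it is suspect" with honest
covariance bookkeeping, and in practice coasts the track on its motion
model through dropouts and spurious detections.  Tail points are not
filtered independently: each track carries the tail of its matched
detection, held from the previous frame when unmatched.  The inflation
factor and the corrupted-frame rule are deliberately simple; an
innovation-based trigger (innovation beyond three gates) also inflates
noise but is rarely reachable under gating.

## Contact identification

Per frame, every animal gets a head circle (centred on the shoulder
keypoint; an optional forward offset along the orientation by a
fraction of the radius is available and defaults to 0) and a tail
circle (centred on the tail keypoint).  The shared radius is

    r = (1 / (alpha * N)) * sum_i || s_i - t_i ||,

the mean shoulder-tail length of the N animals present divided by
`alpha` (default 3) — recomputed **every frame**, so the regions track
animal growth.  Two equal circles intersect iff their centres are at
most `2r` apart; the test is boundary-inclusive for determinism.  A
pair can produce a head-head event and one or two role-tagged
head-tail events simultaneously.  Events are emitted per frame; an
episode view merges events of the same (pair, type, roles) whose frame
gaps are at most `gap_tolerance` (default 5 frames = 0.5 s at 10 fps).
Episodes are a convenience layer: the per-frame table is the primary
output.

## Social networks

Nodes are animal IDs (isolated animals retained); an edge's weight is
the contact frequency between the pair, counted either in per-frame
contact rows (default) or in episodes — the literature rarely states
which unit a published network used, so both are provided.  Networks
can be filtered to one contact type; per-type weights always partition
the all-type weight.  Export formats: GraphML and edge-list CSV;
figures use a seeded spring layout with edge thickness proportional to
weight.

## Evaluation

*Detection*: around every annotated shoulder a circular detection
region is drawn with radius equal to the frame's mean shoulder-to-ear
distance.  Each predicted point is assigned to the nearest region that
contains it (ties to the lower annotation index).  A region with
exactly one assigned point contributes a true positive; extra points
in a region and points in no region are false positives; empty regions
are false negatives, so TP + FN always equals the number of
annotations.  Sensitivity TP/(TP+FN), precision TP/(TP+FP), and
F1 = 2TP/(2TP+FP+FN) follow.

*Tracking*: MOTA = 1 − (FP + FN + IDSW)/N.  The counting is automated:
per frame, tracker points are matched one-to-one to reference points
within a localisation threshold (default: that frame's detection-region
radius, for symmetry with the detection protocol); unmatched reference
points are FN, unmatched tracker points are FP, and an identity switch
is counted when a reference identity's matched track id differs from
its previous one.  A simultaneous pairwise exchange of two identities
is coalesced into **one** switch case (the unit used in the reference
counting of "cases in which the assigned ID of two pigs switched"),
while both per-identity changes remain available as logged events.  N
is the number of reference points presented over the evaluated frames.

## Synthetic pen simulator

The simulator exists so every stage is testable without farm video.
It emulates: a rectangular pen (default 640 x 400 px) with n pigs of
body length 90 px and shoulder-ear offset 18 px; waypoint-following
correlated random walks with per-frame step at most body_length/10 and
heading change at most 15°/frame (a few px/frame, the regime the
constant-velocity tracker assumes at 10 fps); rigid-body separation
(unscripted pairs are projected apart to at least half a body length —
pigs cannot interpenetrate); and scripted approach events that steer a
pair into a guaranteed head-head or head-tail contact inside a stated
frame window (scripted pigs loiter near the pen centre beforehand,
close in early enough for the bounded walk to arrive, and are exempt
from the separation constraint while engaged).  Ground-truth contacts
are the brute-force per-frame region intersections of the generated
poses.

Detector corruption models the failure modes of a real keypoint
detector: per-keypoint Gaussian jitter, per-pig-frame missed
detections plus scripted occlusion episodes, Poisson-distributed
spurious *full poses* (so false positives exercise the tracker, not
just the detection scorer), and shoulder-tail swaps.  Everything is
seeded and bit-reproducible.

What the simulator does **not** emulate: photo-realistic appearance,
postural variety (lying/sitting), body deformation, true social
behaviour beyond scripted approaches, and detector error correlations
(real CNN failures cluster on occlusions and lighting, not i.i.d.
pig-frames).  Passing tests therefore demonstrate the correctness of
the decoding, tracking, contact and scoring logic under controlled
conditions — not field performance of any particular detector.

## Optional detector

The detector module builds the reference encoder-decoder architecture:
25 convolutional layers (3x3, zero padding, stride 1, ReLU), four 2x2
max-poolings to a 1/16-scale latent map (640x400 → 40x25), six stacked
convolutions at the bottleneck, four upsampling stages each followed
by a skip concatenation from the matching encoder level, and a final
sigmoid convolution producing the seven channels; binary cross-entropy
loss with Adam.  Filter widths follow a doubling schedule from
`base_filters` (default 16, i.e. 256 at the bottleneck) and are
configurable, since only the layer/pool structure is fixed.  The
implementation is plain numpy (im2col convolutions with hand-written
backprop), which keeps runs exactly reproducible for a fixed seed and
desk-scale training practical; the test suite trains on 200 synthetic
64x64 single-animal crops for 30 epochs with `base_filters=4`, a
problem size chosen so the whole suite stays interactive on one CPU.
The augmentation set (vertical/horizontal shift up to ±10%, shrink to
0.9x, rotation up to ±15°) applies one joint geometric transform to
the frame and all seven channels, so decoded augmented stacks match
transformed poses; magnitudes are drawn per seed and recoverable.
The rest of the pipeline never imports this module.

## Known limitations

- Fixed animal count; no re-identification after gross tracking
  failure — identities are only as stable as the association.
- Merged body-line components are not split; heavily overlapping
  animals appear as one ambiguous pose until they separate.
- The head region is anchored at the shoulder keypoint (offset 0); a
  true snout region would sit further forward and can be approximated
  with `head_offset_frac`, at the cost of more sensitivity to
  orientation errors.
- The simulator's error model is i.i.d. per pig-frame except for
  scripted occlusions; correlated failure bursts are only reachable
  through the occlusion-episode mechanism.
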