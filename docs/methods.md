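# Methods

## The detection problem

A videofluoroscopic swallowing study (VFSS) records a lateral fluoroscopy
view of a subject swallowing radio-opaque material. The clinically decisive
moment — the pharyngeal phase, when the bolus is propelled from the oral
cavity through the pharynx with the airway protected — lasts about a second
and occupies a small fraction of a recording that can run for minutes.
`vfssdet` localizes every occurrence of the pharyngeal phase in an untrimmed
grayscale video as a set of `[start_frame, end_frame]` intervals with
confidences, using a three-stage cascade:

1. **candidate generation** — dense TV-L1 optical flow flags 20-frame
   windows with strong vertical motion through the mid-frame;
2. **clip classification** — a 3D convolutional network scores each 20-frame
   clip as pharyngeal phase vs. anything else;
3. **sliding-window detection** — classifier scores over a 20-frame window
   at stride 5 are folded to per-frame scores, smoothed, and thresholded
   into intervals.

All video is processed at 15 FPS (30 FPS sources are subsampled by index;
the subsampling rule — frame dropping rather than averaging — is a package
choice, as either reading is defensible). Frame indices are 0-based and
intervals are inclusive; an interval is the frame set `{start, ..., end}`
everywhere, including in the IOU.

## Stage 1: motion voting

Flow is computed per consecutive grayscale frame pair with the TV-L1 solver
from scikit-image at native resolution, giving a displacement field in
pixels with X to the right and Y pointing down the image (verified against
rendered translations). Components are truncated to [-10, 10] px and divided
by 10, so downstream values live in [-1, 1]; truncation happens immediately
after the solve, before any resizing. The solver's parameters (attachment
15, tightness 0.3, 5 warps per scale, 10 iterations per warp, tolerance
1e-4) are library defaults exposed as config keys; results are deterministic
for fixed parameters.

A flow step `t` (pairing frames `t` and `t+1`) *triggers* when the maximum
|Y| inside the central region of the frame exceeds `fth = 0.4` — i.e. raw
motion above 4 px/frame. The central region spans the middle 50% of each
dimension (the pharynx sits mid-frame in a lateral view; the extent is
configurable). A triggering step adds one vote to itself and its eight
nearest steps (radius 4 per side, unit weight — the only symmetric reading
of "eight nearest"; with `vth = 2.5` and unit votes, acceptance therefore
requires a tally of 3). Steps are then visited in descending tally order
(ties: earlier step first, for determinism); a step becomes a candidate peak
if its tally strictly exceeds `vth` and it lies inside no previously
accepted candidate's span. Each peak yields the 20-frame clip
`[clamp(peak-10, 0, T-20), ...]`; at most five candidates per video.
"Not included in other candidates" is read as peak containment (the
alternative, any-span-overlap, is stricter than the wording).

## Stage 2: clip classification

Two inflated-3D-convolution layouts are implemented over a shared skeleton:
7×7×7 stride-(2,2,2) stem → 1×3×3 stride-(1,2,2) maxpool → stage 2 →
1×3×3 stride-(1,2,2) maxpool → stage 3 → 3×3×3 stride-(2,2,2) maxpool →
stage 4 → 3×3×3 stride-(2,2,2) maxpool → stage 5 → average pool → 2-way
linear head with softmax. The **baseline** uses a plain 1×1×1 + 3×3×3
stage 2 and 2/5/2 inception modules in stages 3–5; the **deeper variant**
uses inception modules throughout, 3/4/6/3 per stage, concentrating capacity
early where small fast motion is resolved. An inception module concatenates
four branches — 1×1×1; 1×1×1→3×3×3; a narrower 1×1×1→3×3×3; and
3×3×3-maxpool→1×1×1 — whose widths are fixed proportions of the stage width
W (W/4, W/8→W/2, W/16→W/8, W/8), so a module's output width is W.

Padding is "same"-style (ceil-mode) everywhere except the temporal axis of
the last stride-2 maxpool, which is unpadded: that is the unique assignment
under which 20 input frames reach a temporal extent of exactly 2 and 224 px
reach 7×7 before the final pool, matching the printed 2×7×7 pooling window.
The final pool is implemented as an average over the entire remaining
extent, which at nominal input *is* the 2×7×7 window; this also makes the
two variants' printed pool strides (2,2,2 vs 1,1,1) equivalent, as both
produce a single output cell.

Channel widths are not part of the printed layout. The default schedule
(stem 32; stage widths 64/160/208/240) gives 1,019,943 parameters for the
baseline and 1,370,063 for the deeper variant — computed at build time by
`count_parameters`, in the same ~1.0–1.4 M regime as the original
architectures, with the deeper variant strictly larger under any shared
schedule. The default schedule's count ratio is 1.34; the originally
reported counts (1.228 M / 1.422 M) imply 1.16. The exact widths that would
reconcile both counts are not recoverable from the published layout — a
ratio nearer 1.16 would require widening late stages relative to early
ones, which runs against the variant's stated design intent — so the
schedule stays configurable and the counts are always logged rather than
asserted. Every convolution is followed by batch normalization and ReLU
(declared, not inferred — the standard construction for this family).

The layers are a compact numpy library (im2col + BLAS matmul, manual
backprop, verified against numerical gradients). Training is plain momentum
SGD (momentum 0.9), 2-class cross-entropy, mini-batch 6, cosine
learning-rate decay from 0.1 with a linear warm-start ramp; weight
initialization and batch sampling both derive from the schedule seed, so a
fixed seed reproduces the loss trace exactly. Dropout and weight decay are
not used.

## Stage 3: sliding-window detection

Windows of 20 frames at stride 5 (the last window clamped to the sequence
end) are scored by the trained classifier. A frame's score is the mean over
all windows covering it (unspecified upstream; the mean is order-independent
and unbiased), smoothed by a width-5 centered moving average with edge
replication. Maximal runs of frames with score strictly above
`scoreth = 0.5` and length strictly above `frameth = 5` frames (0.33 s at
15 FPS, a plausible minimum event duration) become detections with
confidence `mean(run scores) + λ·run_length`, `λ = 0.001` — the confidence
formula is not given upstream beyond the hyper-parameter list, and a small
length bonus is the simplest role for λ consistent with confidence-ranked
evaluation. For reviewer export, intervals can be padded by 10 frames on
each side (clamped, unmerged); evaluation always uses unextended intervals.

## Evaluation protocol

Temporal IOU of two inclusive intervals is shared frames over combined
frames. Detections are matched greedily in descending confidence (ties:
earlier start): each claims the unclaimed ground-truth interval with IOU
strictly above 0.3 that minimizes the pair's time error — mean of absolute
start, middle and end offsets, in seconds, with half-integral middles kept
real-valued — breaking ties by higher IOU, then earlier ground-truth start
(the two published criteria do not order themselves; this precedence is a
package choice). A detection whose only above-threshold ground truths are
already claimed is *ignored*: excluded from the precision denominator,
since it neither discovers nor invents an event. No overlap at all makes a
false positive; unclaimed ground truths are false negatives. Counts are
pooled across videos (micro-averaging) before computing precision, recall
and F1; the miss rate is the percent of videos with zero true positives.
Two annotators' interval pairs are merged by endpoint averaging with
half-up rounding, paired in order of occurrence. Reports round half-up to
2 decimals (percentages, seconds) and 1 decimal (miss rate).

## Synthetic data

The generator renders what the cascade assumes about a lateral VFSS scene,
not its radiographic physics:

* a **static background**: soft-tissue gradient, a bright vertical spinal
  column, horizontal tissue boundaries and a few compact bony landmarks
  (vertebral corners, hyoid). The horizontal structures matter: a background
  with only vertical edges makes rigid vertical motion invisible to optical
  flow (the aperture problem), so "coughing" distractors would never fire;
* per **event**, a bright elliptical blob (radii 0.11·H × 0.08·W — large
  enough for the TV-L1 pyramid to resolve its full displacement) descending
  through the central region at a constant drawn speed. Default speed range
  is 5–8 px/frame: below ~4 px/frame an event cannot exceed `fth` after
  normalization by construction, so slower defaults would contradict the
  high candidate recall the cascade is designed around. Events are pairwise
  separated by ≥ 20 frames, placed by joint slack distribution so any
  feasible set of durations is always placeable;
* **distractors**: whole-frame horizontal shift ramps (head translation —
  pure X, casts no votes), vertical jitter alternating 0/magnitude px with
  zero net displacement (2 px default, sub-threshold; 5 px as a *hard
  negative* that fires the vote stage — 5 px is the largest rigid shift the
  flow solver tracks accurately at these frame sizes), and per-frame sensor
  noise. Frames are quantized to 8 bits, so writing PNGs round-trips
  exactly. Everything is deterministic given the spec seed.

All magnitudes are pixels per frame, so their interaction with the
vote threshold is arithmetic, not empirical.

What the generator does *not* emulate — anatomy deforming rather than
translating, exposure changes, interlacing, genuinely ambiguous swallows —
bounds what green tests prove: they validate the cascade's mechanics and
its thresholds' arithmetic, not clinical performance.

## Study sizes in the test suite

The end-to-end suites run 3 seeded replicates of a study with 20 training
and 5 test videos of 72 frames at 48×48 px, events of 8–12 frames at
5–6.5 px/frame, half the training videos event-free with hard-negative
oscillation (these provide the classifier's negative candidates), the deeper
RGB variant at reduced widths (stem 8; stages 16/32/32/32; 44,265
parameters) trained for 300 iterations. At these sizes a full replicate
(flow, harvest, training, detection, scoring) runs in about four minutes on
one CPU. Each harvested candidate contributes two temporally jittered copies
(start ± 5 frames, re-labeled against ground truth, with ambiguous fringes
dropped) so the classifier sees events at the off-center positions the
detection stride produces; event-free videos contribute three fixed
background windows as additional negatives — without these, the classifier
never sees strong horizontal motion, which the vote stage filters out before
it.

## Numerical and degenerate-input choices

* Strict inequalities follow the published wording everywhere a threshold is
  crossed (`> fth`, `> vth`, `> scoreth`, `> frameth`, `IOU > 0.3`).
* Undefined metrics (zero detections or zero ground truths) are NaN with a
  warning, never an exception; JSON reports render them as null.
* `normalize_flow` refuses already-normalized input so the /10 scaling
  cannot be applied twice; `vote_frames` refuses unnormalized input.
* Flow-stream clips for a window ending at the last frame repeat the final
  flow step (a 20-frame window spans 19 pairs).
* Candidate clips at sequence boundaries are shifted inward, never padded;
  all clips are exactly 20 real frames.
* Sort ties anywhere (vote tallies, confidences) break toward the earlier
  frame for determinism.

## Known limitations

* The numpy network trains toy-width models in minutes but is not suited to
  the full-width schedules at clinical scale; no pre-training path exists
  (the published pre-trained rows rely on a large action-recognition corpus
  and are out of scope).
* MP4/AVI decoding depends on an available imageio backend; PNG frame
  directories are the lossless, dependency-free path and the one the tests
  exercise.
* The annotation merger assumes the two annotators produced equally many
  intervals per video, paired in order.
* Detection is offline (whole video in memory); streaming operation would
  need windowed flow and score buffers.
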