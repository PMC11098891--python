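# Methods

## Problem and pipeline

The package classifies Parkinsonian tremor (PT) against other tremor
classes (essential, dystonic, functional, none) and estimates clinical
severity ratings from 2D pose sequences of seated, front-facing subjects.
PT rests in a 3–7 Hz band and is typically unilateral; both facts shape
the design: the video stage amplifies exactly that band, and the network's
channel-squeezing schedule assumes cross-arm information relevance decays
with skeletal distance.

The full pipeline is: Eulerian video magnification (EVM) → pose
estimation (external; the package consumes COCO-17 keypoint JSON) → upper
body selection and origin normalization → 100-frame windowing → graph
network → subclip voting → subject-wise leave-one-out evaluation.

## Eulerian video magnification

Linear EVM on a Laplacian pyramid: each frame is decomposed into
band-pass levels that sum exactly back to the image; each level's
per-pixel time series is filtered with an ideal frequency-domain band-pass
(reflect-padded to suppress edge ringing), scaled by `alpha` and added
back; the pyramid is collapsed and intensities clipped to [0, 1]. Color
is processed on luminance (YIQ) only.

A band-pass (Laplacian) rather than low-pass (Gaussian) level stack is
essential here: because the Laplacian levels partition the image, adding
`alpha` times the temporally filtered levels amplifies in-band motion by
exactly `(1 + alpha)` to first order. A low-pass stack would count the
same signal once per level and overshoot by roughly the number of levels.

Defaults: band 3–7 Hz (the PT range), `alpha = 10`, 4 pyramid levels —
all config-exposed. The magnification factor and filter shape are design
choices; the choice is validated by the oscillating-dot experiment
(±1 px at 5 Hz, `alpha = 10` → tracked amplitude ≈ 11 px; an out-of-band
0.5 Hz control is left unchanged).

`magnify_trajectories` provides the pose-domain equivalent: when the
input is an already-extracted pose stream (as with the synthetic cohort),
amplifying the band-passed joint trajectories by `alpha` reproduces the
effect that video-domain EVM has on subsequently extracted poses. The
synthetic benchmark uses it so that the evaluated system matches the full
video pipeline, not the magnification-free ablation.

## Pose preprocessing

- COCO-17 has no neck; it is synthesized as the shoulder midpoint with
  confidence `min(left, right)` — the convention used by estimators that
  do emit a neck.
- Retained joints (9): neck, shoulders, elbows, wrists, hips. Head/face
  joints are dropped (typically blurred in clinical video); legs are
  irrelevant for upper-body tremor.
- Per frame, the origin is the mean position of neck and both hips; all
  coordinates are expressed relative to it. This removes global
  translation exactly (tested to machine precision).
- A frame is *visible* when every retained joint has confidence ≥ 0.05
  (configurable). Windows (100 frames, non-overlapping, left-aligned) are
  cut only from maximal visible runs; each inherits the video label.
- Optional extras, both off by default and enabled by the synthetic
  benchmark: torso-length scale normalization (divide by the median
  neck–mid-hip distance; removes body-size/camera-distance variation) and
  pose-domain motion magnification (above).
- Severity labels: the video rating is the maximum of the two per-hand
  ratings. Rating tasks use levels {1,2,3} or {1,2,3+} (3+ pools ≥ 3);
  level 0 is excluded. Type tasks drop videos with indeterminate type
  ("Other"); the binary task is PT vs the rest.

## Skeleton graph

Spatial edges: wrist–elbow, elbow–shoulder, shoulder–neck on each side,
plus neck–hip left/right — one connected trunk, 8 edges. No hip–hip edge:
this keeps cross-arm hop distances large (left wrist ↔ right wrist = 6),
matching the assumption that the arms are weakly informative about each
other. Adjacency is row-normalized with self-loops (each row sums to 1),
so a node averages itself and its skeletal neighbors. Temporal structure
is not materialized as edges: the network applies spatial attention per
frame and mixes time only through pooling.

Hop taxonomy: hop 0 = self, hops 1–2 = short-range, hops ≥ 3 =
long-range.

## Network

Input: windows of 100 frames × 9 joints × (x, y, c).

- Input standardization: a per-joint-channel batch normalization
  (`data_bn`, 27 features), the standard first layer of skeleton networks;
  it puts every joint's coordinate distribution on a comparable scale so
  the graph layers' nonlinearities operate near their active region.
- Two graph blocks (64 then 128 channels by default): a locally connected
  attention layer `h_i = σ(Σ_{j∈N(i)} W_ij x_j â_ij)` with per-edge
  weight matrices (no sharing across joints — this is what lets the
  network weight each joint's evidence individually), then batch norm,
  LeakyReLU(0.2) (the σ of the block), dropout 0.2. Weights are shared
  across frames.
- PCSF block: for each target joint i, every joint j's features are
  squeezed by a learned linear map to `C_out(d(i,j))` channels — full
  width at hop 0, `round(p·C)` at hops 1–2, `round(q^d·C)` (floored at 1)
  at hops ≥ 3 — concatenated in node order and fused by a per-target
  linear map back to the block width. `p = 0.5`, `q = 0.25` by default
  (the constraint is only `p ≫ q`; these keep ≥ 1 channel at hop 6 for
  64 channels). Rounding is half-up, deterministic.
- Global average pooling over frames and joints, then a fully connected
  head.
- Losses: softmax cross-entropy (binary), focal loss with `γ = 2` and
  inverse-class-frequency weights (multiclass, where imbalance is the
  norm).
- Optimizer: Adam, lr 0.01 decaying ×0.1 (default at half the epochs),
  batch 8, 500 epochs, dropout 0.2 — the published recipe for this
  architecture family.
- Mirror augmentation (optional): training batches are randomly
  left-right flipped (swap paired joints, negate x), and inference
  averages both orientations. Tremor laterality is arbitrary, the graph
  is symmetric under the swap, and the per-joint weights cannot otherwise
  transfer what they learn about one arm to the other — without this, a
  cohort whose low-severity cases all happen to tremble on one side
  generalizes poorly to the opposite side.

Implementation note: the network is written directly on numpy with
explicit forward/backward passes per layer and gradients verified against
central finite differences. The locally connected and PCSF layers are
evaluated by assembling their block-structured weights into one dense
(V·C_in × V·C_out) matrix per step, so each layer is a single matrix
multiplication; zero blocks encode absent edges.

**Attention readout.** The attention value of joint j at a frame is the
L2 norm of the messages j sends through the second block's attention
layer (its learned per-edge weights applied to its features, scaled by
the adjacency). Aggregation is the mean over frames, then over windows
and folds for cohort summaries. Attention values are raw norms, not
softmax-normalized; only their ranking is interpreted.

**Ablation variants.** `no_pcsf` removes the PCSF block; `no_attention`
additionally replaces the locally connected layers with weight-shared
graph convolutions `σ(Â X W)`.

## Evaluation protocol

One fold per subject (leave-one-subject-out); all of a subject's windows
stay on the same side of the split. Windows are classified independently;
a video's label is the majority over its windows, ties broken by the
highest mean class probability. Binary metrics treat PT as the positive
class; multiclass SE/SP/F1 are one-vs-rest, macro-averaged. Reported
summaries are the unweighted mean over folds and the pooled video-level
metrics over all held-out videos (for a cohort with one video per subject
the two coincide). Folds with no usable test videos after label filtering
are skipped with a warning.

**Tremor-frequency estimation.** Each trajectory axis is linearly
detrended and Hann-windowed; the per-axis power spectra are summed and
the dominant peak in [1, fps/2) located with parabolic interpolation. The
per-axis-spectrum sum (rather than the spectrum of the displacement
magnitude) is deliberate: the norm of a zero-mean oscillation is
rectified and would peak at twice the tremor frequency. A trajectory is
flagged tremor-free when it is essentially constant or when no peak
concentrates at least 20% of the in-band power within ±0.5 Hz.

## Synthetic cohort generator

Each subject is a seated template pose (image pixels, 640×480 frame) with
per-subject limb-length scaling (±10%) and global placement offset
(±40 px) so folds are not trivially memorizable. Tremor is added to the
affected wrist(s) as `A·sin(2πft+φ)` (x-dominant, 30% on y), with the
elbow co-displaced at 40% amplitude; `f ~ U(3, 7)` Hz. Laterality by
class: PT unilateral (random side), ET bilateral, NT none. DT (2–4 Hz,
phase-jittered, with postural drift) and FT (intermittent bursts) are
plausible fixtures that make the multiclass code paths testable — they
are not clinical kinematic models. Severity maps to amplitude as
{1: 2 px, 2: 5 px, 3: 10 px, ≥4: 16 px} (monotone, configurable);
severities are drawn uniformly from {1, 2, 3}. Pose-estimator noise is
i.i.d. Gaussian jitter (σ = 1 px) on every joint plus Markov occlusion
gaps (entry 0.005/frame, mean length 5 frames) during which all
confidences drop below the visibility threshold. Everything derives from
one seed and regenerates byte-identically.

What the generator does **not** emulate: correlated estimator error,
posture changes and task-dependent motion, re-emergent tremor dynamics,
camera motion, multi-person scenes. Passing the synthetic benchmark
therefore demonstrates that the implementation learns and localizes
band-limited lateralized oscillation under noise — not clinical
performance.

## Scaled benchmark

The acceptance benchmark (`spa_pta.benchmark`) uses 30 subjects (15
unilateral PT with severities 1–3, 15 tremor-free), one 10 s video each
at 30 fps, preprocessed with torso scaling and pose-domain magnification,
and a scaled model: block channels (8, 16), 50 epochs, batch 32, mirror
augmentation, float32 arithmetic. These sizes keep a full LOOCV to a few
minutes on one CPU while exercising the identical architecture, losses
and protocol; the published-scale defaults (64/128 channels, 500 epochs,
batch 8) remain the library defaults.

## Numerical choices and degenerate inputs

- Channel rounding: half-up, floor at one channel; `p > q` is enforced.
- Voting ties: highest mean probability, then lowest class index.
- Metrics with empty denominators are NaN and excluded from macro means.
- Constant trajectories: frequency estimator returns tremor-free rather
  than a spurious peak.
- Frames whose origin joints have zero confidence cannot be normalized
  and are flagged not-visible instead.
- Band edges at or above Nyquist, single-frame clips, non-finite features
  and out-of-range labels raise immediately with context.

## Known limitations

- Temporal structure enters only through pooling of per-frame features;
  the model detects amplitude-like statistics, not fine spectral shape.
  Very low-amplitude tremor (≈ 2 px, the severity-1 setting) sits near
  its detection floor without motion magnification.
- The attention readout is norm-based and unnormalized; comparisons are
  only meaningful within a run.
- Severity estimation is classification over pooled rating levels; no
  ordinal/regression head.
- The pose estimators themselves are out of scope; estimator bias that a
  confidence score does not reveal propagates into the features.
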