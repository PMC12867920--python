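# Methods

## Problem and model

The package maps a 25-joint 3D pose sequence (T × 25 × 3 metres, 25 fps,
standardized to T = 100 frames ≙ 4 s) to a cognitive-load score in
[0, 100]. The architecture mirrors how load expresses itself at two time
scales: causal dilated convolutions capture short-window dynamics (joint
angle change rates, limb coordination speed), and a self-attention encoder
captures long-range structure (segment transitions, rhythm). A
whale-optimization loop performs a dual search over hyperparameters and a
feature subset; a small fully connected head produces the score.

## Label construction

Per-sequence load labels are objective composites:

* **Difficulty D** (integer 1–5), a choreographic annotation.
* **Coordination entropy E** (bits): each joint's share of the total
  Euclidean path length over the sequence is treated as a probability
  distribution over the 25 joints; E is its Shannon entropy. The
  per-joint-path-share definition was chosen because it sums to one over
  exactly 25 joints, matching the printed form of the entropy; a motionless
  sequence is assigned E = 0 (no coordination demand), not an error.
  E enters the composite in raw bits (range [0, log₂25 ≈ 4.64]); an
  optional flag z-scores the four components before weighting, since
  whether the factors are individually standardized is genuinely open.
* **LF/HF** and **Δα**: physiological proxies that arrive as numbers.

Composite: y_raw = 0.4 D + 0.3 E + 0.2 (LF/HF) + 0.1 Δα; the corpus is
min-max scaled so min ↦ 0 and max ↦ 100 (an all-equal corpus maps to 0,
the same degenerate rule as coordinate normalization). Rater reliability
uses ICC(2,1) — two-way random effects, absolute agreement, single rater —
the standard form for "k experts each rate all n items"; the perfect-
agreement case is returned as 1.0 directly because the ANOVA F-ratios
degenerate there.

## Preprocessing

* **Frame quality** (video input only): frames with grayscale variance
  < 50 are treated as blurred and dropped.
* **Min-max normalization** per joint and axis to [0, 1], removing dancer
  height (1.55–1.85 m) and body-type scale; a constant channel
  (x_max = x_min) maps to 0 rather than erroring — static joints are
  legitimate.
* **Length standardization** to 100 frames: shorter sequences are linearly
  interpolated; longer ones are cut at the music-beat frame nearest each
  multiple of 100 (uniform cuts when beats are missing) and each segment
  resampled to 100 frames.
* **Gaussian smoothing**: 5-frame window, σ = 0.8, kernel normalized to
  sum 1, reflected edges (reflection avoids boundary attenuation; the edge
  rule is our choice).
* **Augmentation / interference operators**, all seeded and independently
  switchable: temporal scaling with a factor uniform in ±10 %, additive
  coordinate noise bounded by ±5 % of each axis range, and per-frame
  joint-angle jitter up to ±3°. The jitter rotates each bone about a
  random axis (the rotation axis is unspecified in principle, so a random
  axis per joint per frame is used) and rebuilds children by forward
  kinematics, preserving bone lengths.

## Branch decomposition

Joint stream (T × 75), bone stream (T × 72; bone_j = x_j − x_parent(j)
over a 25-node skeleton tree, 24 bones), velocity stream (T × 75; first
differences × fps with the first frame replicated to keep T). The skeleton
tree is configuration: a COCO-style tree extended with spine, hands,
heels/toes and head-top ships as the default, loadable from JSON, and all
operators are topology-agnostic since no canonical 25-joint tree exists.

## Temporal network

Three independent 5-layer causal dilated convolution stacks (one per
stream), dilations [1, 2, 4, 8, 16], each layer conv → LeakyReLU (0.1) →
LayerNorm (ε = 1e−5), zero past-padding. Outputs are concatenated and
linearly fused to a 256-d per-frame feature (default 128 channels per
branch; 384 → 256 fusion).

**Kernel size.** The default is K = 2: the stack's receptive-field
arithmetic (2 frames after the first layer, 32 frames after the fifth,
1 + (K−1)·Σd) only holds at K = 2, while a 3-tap kernel is also described
for the same stack; we resolve the conflict in favour of the receptive-
field statements and leave K configurable.

No residual connections are used inside the stacks, and the three branches
do not share weights.

The encoder lifts 256 → 512 with a linear map, adds fixed sinusoidal
positional encodings (sequence order matters for segment transitions;
switchable off, under which mean pooling is permutation invariant), and
applies 3 post-norm layers of 8-head scaled dot-product attention
(d_k = 512/8 = 64) and GELU feed-forward 512 → 2048 → 512, dropout 0.1
(rate unspecified in principle; 0.1 is the conventional default). The
pooled representation is the temporal mean of the output sequence.

The head applies 300 → 128 → 64 → 1 with ReLU and `100·sigmoid`, so scores
are strictly inside (0, 100). During training the feature mask (the whale
search's 300 indices at full width) gates the pooled encoder output;
without a search the first `head_in` indices are used.

All networks are built on a small reverse-mode autodiff engine
(`poseload.autodiff`) over float64 NumPy arrays, with AdamW
(decoupled weight decay) as the optimizer. Gradients of every primitive
are verified against finite differences in the test suite.

## Training regimen

AdamW, lr 1e−4, weight decay 1e−4, batch 32, up to 100 epochs, early
stopping after 5 epochs without validation improvement, seeded shuffling
and dropout (two runs with one seed produce identical traces). The
weighted MSE gives samples with true load ≥ 70 weight 1.5. The loss is
reduced as the per-batch mean of the weighted terms so the learning rate
is batch-size invariant; the literal sum is available by flag. Non-finite
loss aborts with a diagnostic.

## Whale-optimization dual search

Position = continuous hyperparameter block (learning rate on a log scale,
integers by half-up rounding) ⊕ 512 mask logits in [0, 1]; the mask
decodes to the 300 largest logits, ties to the lowest index. Fitness
= 0.7·MAE + 0.3·FRC, MAE on the validation split (the split choice is
open; validation avoids selection on training error). FRC is
(1/M²)·Σ_{j<k}|r_jk|: absolute correlations, because signed values would
let oppositely-signed redundancy cancel, contradicting the redundancy-
elimination purpose; a signed mode exists behind a flag.

Dynamics per whale and iteration: probability 0.5 of a logarithmic-spiral
move around the best (b = 1, l ~ U[−1, 1]); otherwise A = 2a·r − a with
a(t) = 2(1 − t/max_iter) decides encircling (|A| < 1) vs random-peer
search (|A| ≥ 1). A 10 % floor forces the random-search branch regardless
of |A|, reconciling the stated random-search probability with the |A|
rule. Elitism keeps the best-ever candidate; defaults are population 30
and 50 iterations (100 appears as an alternative cap and is configurable).
The taboo mechanism — named but never specified — is a fixed-capacity FIFO
list of quantized positions; failed evaluations enter it, matching
candidates are re-sampled, and entries expire after 10 iterations (the
"desirability" relaxation re-admitting good regions).

Candidate evaluation is a short proxy run: a ridge regression on the
selected feature columns, scored by validation MAE. This keeps each of
the ~30 × 50 evaluations at milliseconds while preserving the selection
pressure the search needs.

## Synthetic-data generator

Each sequence is a sum of per-joint sinusoids around a shared rest
skeleton, scaled by a dancer height drawn from U(1.55, 1.85) m. Difficulty
drives the generative factors monotonically: per-joint activity follows
w_j ∝ exp(−λ(D)·j/24) with λ falling linearly from 6 (D = 1) to 0 (D = 5),
so easy sequences concentrate motion in few joints (low E) and hard ones
spread it uniformly (E → log₂25); amplitude (0.05 → 0.1 m mean),
frequency (0.8 → 1.8 Hz) and inter-joint phase dispersion grow with D;
lfhf = 1 + 0.5 D and Δα = 0.2 D plus seeded noise. Coordinate noise
defaults to 2 mm per frame, matching the annotation accuracy of the
professional motion-capture corpora the generator emulates; proxy noise
sds are 50× and 25× the coordinate noise (0.1 / 0.05 at default). Beats
are equally spaced at a genre-dependent tempo (88–142 bpm).

True loads are computed by the label chain itself (entropy → composite →
min-max), so label tests exercise the real code path. The generator also
records which 40 of the 512 global feature slots are wired to the load,
via a fixed seeded projection of the standardized factors; the remaining
slots are pure noise. The 70/20/10 split uses globally exact quotas
(largest remainder) with per-genre allocations rounded as close to
proportional as the quotas allow.

**What the generator does not emulate**: biomechanical constraints
(joint limits, ground contact), genre-specific movement vocabulary,
music audio, camera noise or occlusion, and real physiological dynamics —
the proxies are monotone maps of difficulty, not measured signals. Tests
passing on this data therefore demonstrate the correctness and learnability
of the pipeline, not field performance on recorded dance.

## Problem sizes and numerical choices

Experiments run at deliberately reduced widths — 8 channels per branch,
16-d fusion, a 1-layer/32-d/4-head encoder, 24-d head input, 200-sequence
corpora, learning rate 1e−2 — chosen so the full study (training across
seeds, 20 whale searches, permutation tests) completes in minutes on one
CPU while keeping the architecture's structure intact; `ModelConfig`
defaults retain the full-width values. Other numerical choices: float64
throughout; zero past-padding for causal convolutions; sigmoid head biases
initialized at 0 so training starts from score 50; ties in AUC score 0
(the strict pairwise rule) with a half-credit mode for comparison with the
conventional rank AUC; the torso diagonal normalizing PCK is the
left-shoulder ↔ right-hip distance (no canonical definition exists);
mid-range samples (30 ≤ y < 70) are excluded from AUC pairs.

## Known limitations

* Pose estimation from video is out of scope: the package consumes pose
  sequences; the frame-quality filter is the only video-facing piece.
* The 25-joint tree is a constructed default, not an authoritative
  standard; results depending on topology should re-run with the user's
  tree.
* MPJPE/PCK here measure the reconstruction cost of the smoothing stage
  (and any augmentation) against raw coordinates — there is no external
  pose model whose predictions could be scored.
* The NumPy engine is single-threaded and eager; it is sized for the
  reduced-width experiments, not for full-width 512-d training at scale.
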