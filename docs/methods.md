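# Methods

This note records the models implemented, the parameters that matter,
what the synthetic data does and does not emulate, and the choices made
where the design was genuinely open.

## Keyframe extraction

Thermal video at 25 fps is highly redundant. Frames are converted to
grayscale with the ITU-R BT.601 weights (0.299, 0.587, 0.114) and a
frame is selected as a keyframe when the mean absolute intensity
difference to its predecessor exceeds a threshold `T` on the 0–255
scale. We read the inter-frame-difference rule at the frame level (the
scalar mean of the per-pixel absolute differences), the standard form of
the method; a per-pixel thresholding variant would mark pixels, not
frames, and cannot by itself yield a frame selection.

Parameters: `threshold_T` (default 5.0 grey levels — roughly twice the
difference floor of moderate sensor noise, σ ≈ 2–3, so static scenes are
rejected while bird movement of a few dozen pixels is kept); `min_gap`
(default 0, i.e. the plain rule; positive values suppress bursts of
near-duplicate keyframes); `output_size` (default 512×512, bilinear,
aspect ratio not preserved). Only adjacent-pair differencing is
implemented; multi-frame accumulation is out of scope.

Raising `T` can only shrink the selection — this monotonicity, the
symmetry of the difference, and the zero-selection property on static
video are asserted as properties in the test suite.

## Dataset construction

Four aggregation-state categories with fixed ids: 1 chicken-half
(occluded single), 2 chicken-whole (single), 3 chicken-few (touching
group of 2–3), 4 chicken-many (touching group of ≥ 4). Polygons use
pixel-corner coordinates; rasterisation shifts by half a pixel to the
scanline filler's centre convention, which makes the mirror-flip rule
`x' = W − x` agree exactly with flipping the rasterised mask. Annotation
`area` is the rasterised pixel count; `bbox` is the tight box of the
vertices.

Augmentation applies each of five operators once per image (plus the
original: 6× multiplication; 1548 inputs give 9288 images). Photometric
parameter ranges are seed-controlled defaults chosen to be visible but
label-preserving: brightness gain U(0.6, 1.4), Gaussian noise
σ ∈ U(5, 15) grey levels, salt-and-pepper density U(0.5%, 2%), shift
±10% of the image side. The mirror flip is horizontal. Shifted polygons
are clamped to the image and dropped when the clipped area falls below
16 px². Geometric consistency (rasterised transformed polygons ==
transformed rasterised masks) is asserted in tests.

Splitting shuffles images by seed and takes round(0.7·N) / round(0.2·N)
/ remainder, so N = 9288 gives 6502/1858/928. Plain image-level
splitting matches that arithmetic; because it can place augmented copies
of one source image on both sides of the split, `split_dataset` also
offers `group_by_source=True`, which keeps all six variants of a source
together (sizes then deviate slightly from the rounding rule). The
default remains image-level; the grouped mode is the right choice when
the split follows augmentation.

## CBAM backbone

ResNet-v1 bottlenecks (1×1 → 3×3 → 1×1, stride on the 3×3), stages
(3,4,6,3) for depth 50 and (3,4,23,3) for depth 101, group
normalisation (batch-size independent, so single-image CPU training is
deterministic and stable). Channel attention uses one shared bias-free
two-layer MLP (hidden width C/r, ReLU between layers) applied to the
global-average and global-max descriptors, summed and sigmoid-squashed;
spatial attention concatenates the channel-mean and channel-max planes
and maps them with a 7×7 convolution (padding 3). Reduction ratio r
defaults to 16; at reduced widths it is clipped per block to the largest
divisor of the channel count.

CBAM is applied after the residual addition of every bottleneck
(`cbam_placement: post_residual`), reading "the conclusion of each
bottleneck" literally; the conventional pre-addition placement is kept
as `pre_residual`. A width multiplier scales all channel counts so the
identical architecture runs at desk scale; parameter-count bookkeeping
(closed form vs. constructed model) is tested at several widths.
Weights initialise Kaiming-normal from a seeded generator; no pretrained
weights are assumed anywhere.

## AC-FPN neck

The context extraction module (CEM) runs C5 through densely connected
dilated 3×3 convolutions (rates 3, 6, 12, 18, 24), each block consuming
C5 concatenated with all previous block outputs, and fuses the block
outputs with a coarse path by a 1×1 convolution. Two open points are
resolved as follows:

* **Deformable sampling.** The runtime provides no deformable
  convolution kernel, so the CEM blocks use plain dilated convolution
  and log the downgrade; `use_deformable` remains in the config for
  runtimes that have one.
* **The coarse path.** CEM output must match C5's spatial size for
  fusion, so the default coarse path is an identity-resolution 1×1
  projection (`cem_coarse_mode: project`); a literal
  upsample-then-downsample variant (`up2x_down2x`) is kept as an option.

The attention-guidance module applies CxAM then CnAM to the CEM output.
Both compute a row-stochastic position affinity — softmax over flattened
spatial positions of QᵀK (CxAM, projections of the CEM output) or PᵀZ
(CnAM, projections of C5) — scaled by 1/√d for numerical stability, and
add the attended values residually. CnAM deliberately derives its
affinity from C5, as specified, to counteract positional drift
introduced by the context blocks. The attended map is added to the C5
lateral and propagated down the standard top-down pathway (nearest
2× upsampling, 1×1 laterals, 3×3 smoothing, uniform 256 channels,
optional stride-2 P6 for proposals only). With CEM and AM disabled the
neck is exactly a plain FPN, which the tests assert weight-for-weight.

## Detector

Anchors of scales {32, 64, 128, 256, 512} map one-to-one onto P2–P6
with aspect ratios {0.5, 1, 2}. The RPN head is shared across levels;
proposals are merged across levels, deduplicated by NMS at IoU 0.7 and
capped. RoIAlign samples 2×2 bilinear points per bin with no coordinate
quantisation (7² patches for the box head, 14² for the mask head);
RoIs are assigned to pyramid levels by the standard
⌊4 + log2(√area/224)⌋ rule. The box head is two fully connected layers
with classification over 4 classes + background and class-specific box
regression; the mask head predicts per-class 28×28 logits.

Training follows the reference hyperparameters (batch 4, base LR 0.004,
70 epochs, SGD momentum 0.9, weight decay 1e-4 — the optimiser itself is
unreported in the source material and these are the conventional
settings for this detector family, documented as assumptions), with two
standard stabilisers: linear LR warmup from 10% over the first 50 steps
and global gradient-norm clipping at 10. Because short runs see few
RPN-quality proposals, the trainer also appends a configurable number of
jittered copies of each truth box (default 4, jitter 15% of box size) to
the proposal set at training time; this gives the box head non-trivial
regression targets and keeps positives present while the RPN warms up.
It affects training only, never inference.

Losses: binary cross-entropy on sampled RPN anchors (256, half
positive), smooth-L1 (β = 1/9) on positive anchors, cross-entropy and
class-specific smooth-L1 on sampled RoIs (128, quarter positive),
binary cross-entropy on the matched class's 28×28 mask. Checkpoints
store all weights plus the exact config; per-epoch losses are logged as
JSON lines with the seed.

### Desk-scale problem sizes

Full-width ResNet-101 at 512×512 is far beyond interactive CPU budgets
in a numpy runtime, so structural checks (the four ablation variants
{±CBAM} × {FPN | AC-FPN} at 512×512) run at width multiplier 0.125, and
the micro-learnability run uses the `micro_model_config` scaling
(ResNet-50 at width 0.125, 48-channel neck, dilations (1,2,4), 256×256
input, 16 single-bird scenes, ≤ 300 steps). These sizes are package
choices for the test fixtures; the architecture is unchanged and the
parameter-count orderings are width-independent.

## Evaluation

The evaluator reproduces the COCO protocol: detections sorted by score
(stable, index tie-break), greedy one-to-one matching per category at
IoU thresholds 0.50:0.05:0.95 with non-ignored truths preferred,
area-band ignore rules, 101-point interpolated precision, and the
mean-over-thresholds/categories summaries. Reported: AP, AP50, AP75,
AP_M (32²–96² px²), AP_L (> 96² px²), AR10 (10 detections per image),
AR_M, AR_L (100 detections). Chickens image as medium or large objects,
so the small band is computed internally but not reported; empty bands
carry the −1 sentinel and are excluded from means. AR10 caps detections
per image jointly over categories. Per-category "segmentation accuracy"
is reported as per-category segmentation AP50 and labelled as such.

Box IoU uses continuous areas; mask IoU uses dense pixel counts
(vectorised), with run-length encoding used for serialisation and
round-trip equivalence asserted in tests. The whole module is checked
to 1e-4 against an independent brute-force reference implementation
(explicit loops, naive accumulation) on randomised predictions over 50
synthetic scenes, in both bbox and segm modes.

## Synthetic scenes

Warm bodies are axis-rotated ellipses with a smooth radial intensity
falloff (peak U(150, 235) grey levels on a 60-level background),
optionally clustered; vertical dark bars of configurable count/width
emulate cage occlusion; Gaussian sensor noise (σ = 5 by default) is
added last. Touching blobs (dilation-by-1 overlap) merge into one
instance whose category follows the aggregation rule; an isolated blob
with more than 30% of its area under bars becomes chicken-half.
Ground-truth polygons are traced from the pre-noise visible masks and
the stored truth masks are the rasterisation of those polygons, so the
two agree exactly by construction. Default dataset sampling (3–9 blobs,
cluster probability 0.15–0.55, 0–5 bars) reproduces the real flock
imbalance whole > few > many, with half rarest.

The generator emulates the statistical structure the pipeline assumes —
brightness contrast, occlusion, clustering, category imbalance — but not
feather texture, radiometric calibration, perspective, or background
clutter such as feeders. Passing tests therefore demonstrate pipeline
correctness and learnability on this structure, not field performance on
farm footage.

Videos repeat a static scene and displace the flock by a fixed offset at
each planted motion frame (the displacement persists), so exact recovery
of the planted set is well-defined for any threshold between the noise
floor and the motion magnitude.

## Numerical choices and limitations

* float32 throughout the network; gradient checks run at 3% relative
  tolerance against central differences.
* Ties in max-pooling gradients are split evenly; NMS and matching break
  ties by index; all stochastic steps take seeded generators.
* MP4 decoding requires an optional imageio plugin; without one, frames
  must be supplied as image directories.
* Training at full width/resolution is possible but impractically slow
  in this runtime; the numpy engine is single-threaded apart from BLAS.
* The evaluator's small-object band is implemented but unreported, and
  crowd (RLE `iscrowd=1`) ground truth is out of scope.
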