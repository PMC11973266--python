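# Methods

This note documents the model implemented in `pointspv`, the choices made
where the design was genuinely open, what the synthetic data does and does
not emulate, and the numerical conventions the code relies on.

## Pipeline and coordinate conventions

All image coordinates are 0-based `(row, col) = (y, x)` with the origin at
the top-left; gaze-log CSVs store `x` = column and `y` = row. Images are
float arrays in [0, 1].

The data flow is: segmented image → viewing point (uniform over the
object mask) → patch `I` and background-free twin `I′` → encoder →
binary activation map → simulator → phosphene frame → blind unit
(features + class probabilities), with the sighted unit providing frozen
reference features of `I′`.

### Point sampling

Sampling is uniform over mask-foreground pixels. When a sampled point
lies within half a patch of the image border, the crop window is
*clamped* (shifted to lie fully inside the image) rather than padded, so
every patch contains only real pixels; the stored patch center remains
the sampled point. Patch datasets are split train/validation at the
source-image level by default so near-duplicate patches from one object
cannot leak across the split; a patch-level mode
(`split_level="patch"`) exists for sensitivity analyses.

### Encoder

The architecture is fixed: 13 layer groups, all 3×3 kernels with stride 1
and padding 1 — four conv groups ramping 3→8→16→32→64 channels (groups 3
and 4 followed by 2×2 max pooling), four conv-BN-act-conv-BN residual
blocks at 64 channels (activation after the skip addition), a decoder
ramp 64→32→16→8→3→1 (group 9 pooled; groups 12–13 without batch norm),
leaky ReLUs (slope 0.01) everywhere except the final sigmoid.

Three 2× poolings cannot map a 100 px patch onto a 32×32 grid, so the
input is first resized (bilinear) to `internal_size = 8 × grid_size`
(256 for the default 32×32 grid). This preserves both printed sizes —
100×100 input patch and 32×32 map — at the cost of an explicit resize.

Binarization follows "sigmoid output, Heaviside stimulation": the sigmoid
activations are thresholded at 0.5 with a *strict* inequality (values
exactly at threshold map to 0), and training uses a straight-through
estimator — the backward pass treats the step as the identity on the
sigmoid activations. Tests verify that this backward equals the backward
of the same loss applied to the soft map directly.

The output conv's bias is initialized to −1.5 so a freshly initialized
encoder emits *sparse* maps (σ(−1.5) ≈ 0.18, almost all elements off)
rather than ~50%-on noise. Early joint training is markedly more stable
this way: the pretrained blind unit is not forced to fit frames of dense
random dots before the encoder has learned anything.

Batch normalization uses standard running statistics (momentum 0.1);
inference runs in evaluation mode with frozen running estimates.

### Simulator

Dots are placed cell-centered: element (r, c) peaks at pixel
((r+0.5)s, (c+0.5)s), s = frame_size / grid_size. The default dot profile
is an isotropic Gaussian (σ = s/4) truncated at radius s/2 − 1, i.e.
strictly inside its own grid cell; a flat disk profile is available. The
truncation radius guarantees that phosphenes of adjacent electrodes never
touch, so the number of connected bright blobs in a frame equals the
number of active elements — a property the tests exploit as an oracle.
Peak brightness is 1.0, matching the binary-activation assumption.
Rendering is a Kronecker expansion of the map by the dot template
followed by a clip to [0, 1]: linear before the clip, deterministic, and
differentiable along the training path.

### Recognition units

The backbone abstraction is a list of stages with a split index; the
feature extractor is `stages[:split]` and the classifier
`stages[split:]`, sharing modules so composition reproduces the full
network exactly. Backbones are pluggable via a registry. The default is a
small 8-stage residual network (six pooled conv/residual stages, global
average pooling, linear head) with split index 4, trained from scratch on
synthetic scenes; it accepts any input size divisible by 64. Large
pretrained classifiers can be registered through the same interface, with
a split after their early, spatially coherent stages.

The two feature paths must produce identically shaped maps for the
perceptual loss. The sighted input (a patch, possibly smaller) is
therefore resized to the simulator frame size before feature extraction.
Phosphene frames are single-channel; they are replicated to three
channels and normalized with the same affine convention as patches
(mean 0.5, scale 0.5).

The sighted unit holds a *deep copy* of the extractor, frozen
(`requires_grad=False`, eval mode); its weights are asserted bit-identical
before and after every fit.

### Losses, routing and optimization

`L_P` is the squared L2 difference of the two feature maps divided by the
element count W·H·C, averaged over the batch; `L_CE` is softmax
cross-entropy with mean reduction. The blend is `L = γ·L_P + (1−γ)·L_CE`,
γ = 0.75 by default. The perceptual tap point is the split layer — one
tap, not a multi-layer sum.

Routing: encoder and blind-extractor parameters receive ∇L; blind
classifier parameters receive the *unweighted* ∇L_CE; sighted parameters
receive nothing. For γ < 1 this is computed with a single backward pass
followed by rescaling the classifier gradients by 1/(1−γ) (algebraically
exact); for γ = 1 a second backward pass supplies the classifier's
cross-entropy gradient while the extractor/encoder keep the pure
perceptual gradient.

The optimizer is Adam. The library default learning rate is 1e-4 with
batch size 16 and 5 epochs; every value is exposed in `LossConfig` and
recorded in run manifests. Divergence (non-finite loss) aborts with a
diagnostic. The best-validation checkpoint is retained alongside the
final weights. With a fixed seed, runs are deterministic (the only
randomness sources are seeded numpy generators; bit-level reproducibility
holds in single-threaded numerical mode).

### Backbone pretraining

`pretrain_backbone` stands in for large-scale pretraining of the
recognition backbone: it trains the surrogate as a plain classifier on
the training patches before the split. Batches mix two views of each
object — the clean background-free patch, and the object silhouette
max-pooled onto the electrode grid and rendered by the simulator — so the
feature space covers both the sighted input domain and dot-pattern
stimuli before joint training. Joint training then mostly has to teach
the encoder, which is what the five-epoch desk-scale budget allows.

## Desk-scale configuration

`desk_scale_configs()` returns the scaled-down study setup used by the
end-to-end experiments and tests: 128×128 scenes, 64 px patches, an 8×8
electrode grid rendered into 64×64 frames, Adam at 1e-3, batch size 4,
5 joint epochs after 25 backbone-pretraining epochs. These sizes are
chosen so a complete 3-seed training study (80 scenes × 5 viewing points
= 400 patches) runs in a few CPU-minutes while preserving every
structural property of the full-scale model (binary bottleneck,
non-overlapping dots, routed losses). The full-scale geometry
(100 px patches, 32×32 grid, 256×256 frames) is the library default and
is exercised by the structural tests; training it end to end is a matter
of compute, not code.

## Synthetic data: what it emulates, what it does not

`generate_scene` renders one target object from one of K shape families
on a low-contrast filtered-noise background (a plain-white mode exists to
reproduce ceiling-effect conditions): class 0 is a roundish blob with
low-order boundary wobble and 2–4 protrusions; classes k ≥ 1 are
elongated ellipses whose aspect ratio grows with k. Object color is
pushed at least 0.2 away from the background mean per channel, with mild
internal texture. The mask delimits the rendered shape exactly. The two
default families are separable by coarse shape statistics: a hand-written
moment classifier (square root of the second-moment eigenvalue ratio,
threshold 2) reaches ≥ 90% on 200 scenes, which the tests verify.

`generate_gaze_log` emits alternating saccade/fixation events with
plausible durations (20–60 ms and 150–400 ms), fixation centers falling
in the object's bounding box with probability 0.75, and a response time
after the last sample.

What this does **not** emulate: photorealistic object appearance,
within-class texture/pose variability of natural categories, occlusion,
human oculomotor dynamics (main-sequence saccades, drift, microsaccades),
or any dependence of gaze on the displayed representation. Passing the
end-to-end tests therefore shows that the optimization machinery works
and that the encoding preserves coarse shape through a binary phosphene
bottleneck — not that the learned encoder would transfer to natural
images, nor that human observers would reach any particular accuracy.

## Behavioral metrics

Coverage uses unnormalized Gaussian kernels with peak 1 and σ = 50 px
(σ is interpreted in pixels), composed by per-pixel maximum and averaged
over *all* pixels of the stimulus image. Peak-1 kernels are the only
choice consistent with a statistic that can reach exactly 100% when
every pixel is fixated; a density-normalized kernel could not. Coverage
is computed in float64; it is monotone under adding fixations and
invariant under duplicating them.

Saccade counts are consumed from the trial records, not detected from raw
eye traces — event detection is the recording software's job and out of
scope here.

The repeated-measures ANOVA handles one within-subject factor with two
levels (the two representation methods), fitted via the standard
repeated-measures machinery; its F equals the squared paired-t statistic
on (1, n−1) degrees of freedom, which the tests check against an
independent paired-t computation. Degenerate inputs (zero within-pair
variance) are resolved analytically: identical conditions give F = 0,
p = 1; a constant nonzero shift gives an infinite F. Four metrics are
tested separately with raw p-values; Holm-adjusted values are available
behind a flag.

## Gaze-contingent rendering

The offline renderer reproduces the display logic frame by frame: crop a
patch at the gaze location (clamped at borders), process it with the
selected method, resize into the aperture's bounding box, mask with the
circular aperture {p : ‖p − gaze‖ ≤ r}, and composite on a black screen.
The aperture radius defaults to half the patch size. Frames are rendered
during saccades as well (the display updates continuously); a flag blanks
them for fixation-only visualizations.

The Canny baseline takes thresholds on the 8-bit intensity scale
(defaults 100/200, fully configurable) with a Gaussian prefilter of
σ = 1 px. By default the edge map is max-pooled onto the electrode grid,
binarized and rendered by the same phosphene simulator, so both methods
produce geometrically identical dot-style frames; a `raw_edges` mode
shows the resized edge map directly for sensitivity analyses.

## Known limitations

* The phosphene model is deliberately minimal: homogeneous, equally
  sized, binary dots. Cortical magnification, current spread, temporal
  dynamics and electrode dropout are out of scope; the simulator is
  pluggable to admit richer models.
* The perceptual reference is a frozen early feature extractor; if the
  backbone is weak, the perceptual loss is only as informative as those
  features.
* The numpy engine is single-process and CPU-bound; it is sized for the
  desk-scale geometry. Full-scale (32×32 grid) training is supported but
  slow.
* `LossRecord.val_accuracy` is measured on the patch validation split of
  the synthetic task, which is far easier than natural-image object
  discrimination.
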