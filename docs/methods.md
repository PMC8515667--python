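# Methods

## Problem setting

CBCT volumes used for image guidance in thoracic radiotherapy carry
scatter- and motion-induced artifacts (streaking, shading, cupping) and
systematically distorted HU values — most visibly a lung that reads
~150 HU too dark.  Because CT–CBCT pairs of the thorax cannot be
aligned exactly (breathing, organ filling), the package treats
CBCT → CT translation as an *unpaired* problem: two generator/
discriminator pairs trained with least-squares adversarial losses,
cycle consistency, and identity constraints.  A paired conditional
mode exists as a baseline for datasets where registration is trusted.

## Generator and composition

Each generator has a shared encoder (7×7 stem, two stride-2 3×3
convolutions, then residual blocks) and two decoder branches (each: two
stride-2 transposed convolutions, then a head).  The content head is a
7×7 convolution to n−1 channels through tanh; the attention head is a
1×1 convolution to n channels through a channel softmax.  With
attention weights A (per-pixel simplex) and content channels C, the
output is Σ_f C_f·A_f + x·A_bg.  Two consequences hold by construction
and are enforced as tests: the output is a convex combination of
[−1, 1]-bounded terms and therefore bounded, and forcing A_bg ≡ 1
reproduces the input exactly.

Design choices where the design was genuinely open:

* **Residual-block width.** The blocks run at the encoder output width
  (4× the base channel count).  A narrower setting would be
  dimensionally inconsistent with the surrounding layers.
* **Independent decoder branches.** Content and attention each own a
  full upsampling path; sharing the upsampling would entangle the two
  outputs' feature statistics.
* **Background channel.** By convention the last attention channel is
  background; only the role, not the index, matters.
* **Background-biased initialization.** Weights are zero-mean Gaussian
  (σ = 0.02, seeded); biases are zero except the attention head's
  background logit, which starts at +3 (`background_bias`).  The
  composition therefore begins close to the identity and the attention
  branch learns *where* to admit generated content, rather than first
  spending its training budget re-learning the pass-through.  With a
  cold start, short training runs improve MAE but lose SSIM — the
  generator has not yet recovered local structure; the warm start
  removes that failure mode.  Setting `background_bias=0` restores the
  cold start.
* **Content-head activation** is tanh; the output-boundedness contract
  requires *some* squashing activation, and tanh matches the [−1, 1]
  intensity domain.
* **Padding**: reflection for the 7×7 stem and residual blocks (avoids
  dark frames at volume edges), zero elsewhere.
* **Discriminator**: the 70×70-receptive-field patch design (4×4
  kernels; strides 2,2,2,1,1; leaky-ReLU 0.2; no normalization on the
  first layer).  Patch scores are averaged per image *before* the
  squared LSGAN penalty, so one verdict judges the whole image; the
  per-patch alternative is available via
  `TrainingConfig(patch_reduction="patch")`.
* **Identity terms** use the full attention composition (the same
  generator applied to same-domain input); masks are not bypassed.

## Training regimen

Adam with β = (0.5, 0.999), initial learning rate 10⁻⁴, batch size 1;
the rate is constant for the first `decay_start` epochs, then decays
linearly to zero at `epochs` (default 100 epochs, decay from 50).
Unpaired slice pools are reshuffled independently every epoch with
seeded permutations; one epoch visits the larger pool once and wraps
the smaller.  Per iteration the two generators take one joint step on
the full objective, then each discriminator steps on its own loss
against detached generator outputs; parameter isolation between the
two updates is asserted by test.  No historical-image buffer is used
for discriminator updates by default (`use_image_pool` enables a
standard 50-image pool).  The `cyclegan` mode differs from `aggan`
*only* in disabling the attention branch, so comparisons isolate the
attention mechanism; the `pix2pix` mode keeps the same generator and
the LSGAN form and adds a λ = 100 paired L1 term.

Everything is reproducible given the config seed: weight
initialization, shuffling, and the phantom data itself.

## Intensity handling

HU values are clipped to [−1000, 1500] (thoracic window; values above
1500 HU are saturated) and mapped affinely to [−1, 1]; the inverse map
is exact on the window, and the round trip is tested to 10⁻⁹.  Axial
slices are resampled to the training resolution with bilinear
interpolation, with a Gaussian anti-aliasing prefilter when
downscaling; the interpolator choice is configurable at the call site
because upstream resampling conventions vary.  Volumes are stored
(z, y, x) with axis-aligned geometry only — direction cosines beyond
axis alignment and image registration are out of scope; the synthetic
data are aligned by construction.

## The synthetic thorax phantom

`PhantomSpec` voxelizes an elliptical soft-tissue body, two lung
ellipses, a spine and rib cross-sections of bone, and air outside.
Tissue HU means default to phantom CT measurements — lung −755, bone
+716.2, soft tissue −27.5 — with Gaussian texture noise (40/60/25 HU)
that stands in for parenchymal texture.  Cohorts get 5% seeded jitter
on ellipse axes and centres so volumes differ like patients do.

`ArtifactSpec` layers the CBCT degradations additively in HU before a
final clip, each component independently switchable:

| component | default | shape |
|---|---|---|
| lung shift | −110 HU | constant inside the lung ROI |
| cupping | −40 HU | raised-cosine radial profile, zero at centre |
| streaks | ±60 HU, 6 per slab | narrow ridges through the centre, random angles per 8-slice slab, alternating sign |
| shading | −30 HU | linear ramp along +y |
| noise | σ = 25 HU | white Gaussian |

The amplitudes are calibrated only to reported ROI statistics: the
composite lung mean lands near −900 HU (≈ −145 HU below the CT lung,
the reported CBCT lung depression) and the soft-tissue mean drops below
its CT value, reproducing the orderings seen in patient cohorts.  The
zero-amplitude spec is a bit-exact identity, and component deltas sum
to the composite delta before clipping — both tested.

What the phantom does *not* emulate: projection/reconstruction physics
(no Monte Carlo or FDK), respiratory motion, correlated noise,
anatomical detail (airways, vessels, tumours), or registration error
between CT and CBCT.  Passing the end-to-end benchmark therefore shows
that the training loop, objectives and attention mechanism work as
designed on artifacts of realistic magnitude and spatial structure —
not that clinical-grade image quality is achieved on real patients.

`synthesize_dose` produces a smooth Gaussian dose ball (maximum =
prescription × (1+hotspot) at the target voxel) purely as gamma-analysis
input; no treatment planning is modelled.

## Evaluation stack

* **MAE** in HU, optionally masked.  **PSNR** in dB and **SSIM** use a
  data range of 2500 HU (the clipped dynamic range) by default; the
  value is recorded in every report because conventions differ.  SSIM
  is computed slice-wise on axial planes (11×11 Gaussian window,
  σ = 1.5, K1 = 0.01, K2 = 0.03) and averaged; a 3-D-window variant is
  available.  Metrics cover the whole clipped volume by default, with
  a mask option, since inclusion of outside-body air is a reporting
  choice.
* **ROI statistics**: mean and population SD per label (1 = lung,
  2 = bone, 3 = soft tissue).  Cohort "mean ± SD" is across volumes.
* **Paired Wilcoxon signed-rank**: exact null enumeration for n ≤ 12
  without ties or zeros, normal approximation with correction
  otherwise; all-zero differences return a degenerate flag instead of
  a p-value of convenience.  Significance threshold 0.05.

## Gamma analysis

The 3-D gamma index uses global normalization (dose-difference
criterion as a percentage of the maximum reference dose) by default,
matching the relative-difference convention; local normalization is an
option.  The search evaluates candidate offsets on a uniform grid
(step `dta/10`, ball radius `3·dta`, both configurable) with trilinear
interpolation of the evaluated dose and edge clamping; offsets are
visited in order of increasing length with a sound early-termination
rule (stop when the distance penalty alone exceeds every voxel's
current minimum), so the optimized scan provably equals the exhaustive
search — which is also verified against an independent full-search
oracle in the tests.  The low-dose threshold defaults to 10% of the
reference maximum and is always recorded, as no universal convention
exists.  When grids disagree geometrically the evaluated dose is
resampled onto the reference grid (trilinear) first.  Passing rates
are monotone across 1 mm/1% → 2 mm/2% → 3 mm/3% by construction
(tested on random pairs).

## Problem sizes used by the test suite and acceptance script

The default architecture (base 64 channels, 9 residual blocks,
256×256 slices) is CPU-expensive, so the automated benchmark trains a
width-reduced configuration chosen once: 10 phantom volumes of ten
64×64 axial slices (8 train / 2 held out), generator with 8 base
channels and 2 residual blocks, discriminator with 8 base channels,
n = 10 attention masks, 20 epochs with decay from epoch 10, seed-
pinned.  This preserves every structural element of the full model —
two cycles, both branches, all loss terms, the schedule — at a scale
that trains in a few minutes.  Gamma correctness checks run on 16³
grids with a coarsened search (radius 1.5–2 × dta, step 0.25–0.5 × dta)
so the exhaustive oracle stays cheap.

## Known limitations

* Networks run on a single CPU in float32; no batching (batch size 1
  is also the reference regimen) and no GPU path.
* Axis-aligned geometry only; no DICOM spatial registration, FOV
  cropping, or resampling between modalities.
* The phantom's realism limits, listed above, bound what synthetic
  benchmarks can claim about clinical data.
* Checkpoints store raw weight arrays keyed by module path
  (schema-versioned); architectures must match exactly on load.
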