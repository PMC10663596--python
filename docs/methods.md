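# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices made where the design was genuinely open, and the
limits of what the phantom experiments demonstrate.

## Data model and conventions

A subject is a 4D grid (X, Y, Z, C) of diffusion attenuation values with an
FSL-style gradient table (one b-value per channel, unit direction vectors
for b > 0) and a tissue-label grid (background / white matter / gray matter
/ CSF). All computation happens in voxel space with 0-based indices; the
NIfTI affine is carried through for round-tripping only, because the
pipeline assumes already-registered, masked input.

Normalization maps the signal into [0, 1], the input range the
sigmoid-output networks require. The default is the physical b0-ratio
S/S₀ (each diffusion-weighted channel divided by the unweighted channel
inside the brain mask, clipped to [0, 1]); a global-max mode exists for
data without a b≈0 channel. Normalization is per subject — a per-dataset
switch was considered and rejected because per-subject scaling removes
inter-scan intensity offsets, which is what the fixed thresholds
downstream presuppose. The b≈0 channel is consumed by normalization and
not fed to the networks: the model input is the C diffusion-weighted
channels only. A b-value ≤ 50 s/mm² counts as unweighted.

## Synthetic phantom

The phantom exists so that training, evaluation and the acceptance run
need no external data. It emulates the statistical structure the models
rely on, not brain anatomy:

- **Geometry**: nested ellipsoids — brain envelope, gray-matter shell,
  white-matter core, central CSF ventricle — on a default 32×32×20 grid
  (clinical single-shell acquisitions of the kind this method targets are
  ~90×90×54 voxels with 64 directions; the default is a desk-scale
  stand-in and all sizes are configurable).
- **Signal**: single-tensor model S = S₀·exp(−b·gᵀDg) with axially
  symmetric tensors per tissue: WM with MD 0.75·10⁻³ mm²/s and FA 0.65,
  principal direction tangent to concentric shells (smooth, anisotropic);
  GM (0.85·10⁻³, isotropic) and CSF (3.0·10⁻³, isotropic). Eigenvalues
  come from the closed form d = FA·s/√(3 − 2FA²) with s = 3·MD.
- **Noise**: Rician magnitude noise (|S + n₁ + i·n₂|, n ~ N(0, σ²)),
  σ = 0.02·S₀ by default, because magnitude MRI noise is Rician, and the
  b0-ratio normalization then produces realistically noisy attenuations.
- **Lesions**: an ellipsoid with mean diffusivity multiplied (default
  1.6–2.4×) and FA scaled down (0.2–0.5×), emulating the increased free
  water and fiber disruption of edema/tumor. Centers are drawn inside the
  WM core, semi-axes 3–6 voxels.
- **Cohorts**: per-subject jitter of the geometry fractions (±5%) and
  noise level (±20%), all driven by one seed through spawned substreams,
  so cohorts are bit-reproducible.

What the phantom does **not** model: gyrification, partial-volume mixtures,
crossing fibers, multi-shell acquisitions, susceptibility/motion artifacts,
and — most importantly — realistic tumor texture and infiltrative margins.
Phantom lesions are homogeneous and geometrically simple, so scores here
are upper bounds on task difficulty: passing tests shows the pipeline is
implemented correctly and that the methods behave as designed on data
satisfying their assumptions, not that they reach any particular accuracy
on clinical data.

## Denoising VAE

3D strided-convolution encoder (kernel 3, stride 2, instance
normalization, LeakyReLU 0.01 after every convolution), dense heads for the
latent mean and log-variance, mirrored transposed-convolution decoder, and
a sigmoid (default) or linear output. Channel widths default to
32-64-128-256 at full scale; the phantom-scale experiments use 8-16 with
latent sizes 8–32. The exact layer plan is this package's own design;
affine-free instance normalization was chosen over batch normalization
because training batches of 4 make batch statistics noisy.

Loss: masked MSE over in-brain voxels plus ω·KL with ω = 1.22·10⁻⁵, i.e.
the KL term is only lightly weighted so the focus stays on reconstruction.
Optimizer: Adam, initial learning rate 1e-4 (full scale; 1e-3 at phantom
scale where gradients are far less noisy), decayed by γ = 0.95 per epoch;
500 epochs and batch size 4 are the full-scale defaults. The checkpoint
minimising validation loss is restored after training. Training uses
sampled latents; inference uses the posterior mean so anomaly maps are
deterministic.

Inputs are zero-padded to the nearest stride-compatible grid; padding is
excluded from the loss via the brain mask and cropped from outputs.

The model trains as a plain autoencoder on clean healthy volumes: the
"denoising" behaviour at test time is the failure to reproduce
out-of-distribution structure, which is precisely the anomaly signal.

## Residual map

Per voxel the C signed channel residuals are summed first and the absolute
value taken afterwards. Summing first lets zero-mean channel noise cancel
(≈√C noise suppression) while a lesion, which shifts all channels in the
same direction, accumulates. DAE residual maps are min-max normalized over
the evaluation mask by default so that fixed thresholds such as 0.3 are
comparable across subjects (the alternative — raw residuals — is a config
switch); discriminator outputs are already probabilities and are used raw.
Voxels outside the evaluation mask are set to NaN (a sentinel excluded
from every threshold and metric), never zero, so they cannot masquerade as
"confidently healthy".

## Just-out-of-distribution injection

Per corrupted image the patch count is 0/1/2 with probabilities
0.2/0.6/0.2; each patch is an ellipsoid with uniformly random semi-axes
(2–8 voxels at phantom scale), uniform SO(3) orientation (z-y-z Euler
angles with cos β ~ U(−1,1)), centered on a random in-brain voxel and
clipped to the brain mask — patches may straddle tissue boundaries but
never paint background. Noise values use the per-subject mean μ and
standard deviation σ of pooled in-brain signal (CSF included by default,
excludable): normal N(m, σ²) or uniform over total width σ (m ± σ/2 — the
stated "range" is read as width; m ± σ is a config switch), with m = μ or
μ/2. Spatial structure: independent per voxel and channel (random), one
draw per channel (directional), or one draw per voxel (isotropic); the
same spatial support applies to all channels. Values are clipped to [0, 1]
to stay inside the models' input range. Each training subject is expanded
into 4 independently corrupted copies, drawn once before training
(per-epoch resampling is available).

## RecDiscNet

The reconstruction stage reuses the VAE architecture family without the
variational heads (deterministic bottleneck, sigmoid output). The
discrimination stage is a 3-stage U-Net taking the 2·C-channel
concatenation of input and reconstruction and emitting one logit per
voxel; its first stage downsamples immediately and a final transposed
convolution restores full resolution, which keeps the receptive field
while making CPU training tractable.

Loss: masked MSE between reconstruction and the **clean** volume plus
ω-weighted voxelwise BCE (log-sum-exp stabilised) against the artificial
groundtruth, over in-brain voxels. ω defaults to 1; the positive-class
weight p₁ defaults to the per-batch negative/positive voxel ratio,
the standard compensation for class imbalance (both configurable, since
no canonical values exist). The two stages are optimized jointly on the
summed loss by default — discriminator gradients flow into the
reconstruction net through the concatenation — with a "detached"
sequential mode available. Optimizer, batch size, scheduler and
checkpointing follow the DAE.

## Thresholding and post-processing

- **Fixed**: 0.5 for discriminator probabilities (half the output range),
  0.3 for normalized residuals (sensitive to small deviations).
- **Otsu**: 256-bin histogram over the masked score range, maximizing
  between-class variance; ties resolve to the lowest qualifying bin edge.
- **Pooled maximum**: T = max(I ∗ f_local) with a cubic local-average
  kernel — 16³ at full scale, 5³ at the 32-voxel phantom scale (the same
  fraction of the grid). Stride-1 "valid" windows only: zero-padding would
  dilute window means toward the brain edge, and block pooling is
  available as an option. Implemented exactly via integral images.
- **Youden / Dice-optimal** (supervised; used only to compare model
  architectures): exhaustive scan over candidate cuts placed at midpoints
  between sorted unique scores — exact below 10⁵ voxels, a 512-point
  quantile grid above. Youden ties resolve to the lower threshold (higher
  sensitivity).

Binarization is strict (score > T). Post-processing is morphological
opening with the full 3×3×3 cube, which removes isolated misclassified
voxels (the dominant failure mode of residual maps near CSF boundaries).

## Evaluation

Metrics are confined to white + gray matter; CSF/ventricles are excluded
because free water is trivially "anomalous" under a diffusivity criterion.
Dice is reported raw and post-processed; two empty masks give Dice 1
(possible on healthy phantoms). AUROC is computed per subject with
rank-average tie handling and aggregated as unweighted mean ± population
std over subjects (per-subject-then-aggregate was chosen over pooling all
voxels because the ± spread across subjects is the quantity of interest).
Cross-validation splits the healthy cohort into 7 random subsets (28
subjects → folds of 4); each fold trains on the rest with its subset as
validation for checkpoint selection, then scores every evaluation subject.

## Numerical engine

The networks run on a purpose-built numpy engine: strided 3D convolution
via cached gather indices (im2col), transposed convolution as its exact
adjoint through the same index table (verified by the inner-product
identity in the tests), affine-free instance normalization, LeakyReLU,
dense layers, and Adam with exponential learning-rate decay. Float32 is
the training dtype; gradient-check tests switch the engine to float64 and
verify every layer against central finite differences. Convolution column
matrices are regathered during the backward pass instead of being cached,
which bounds peak memory at batch size 4. All randomness flows through
explicitly seeded numpy Generators, so training is bit-reproducible.

## Problem sizes used in tests and the acceptance run

Unit and training tests run at 16³ voxels with 6 channels; the end-to-end
acceptance experiments use a 28-subject cohort at 32×32×20 with 8
channels, a latent-32 DAE trained 40 epochs, and a RecDiscNet (mix/half
injection) trained 15 epochs, evaluated on 6 held-out lesioned phantoms
and 3 freshly corrupted held-out subjects. These sizes were chosen as the
smallest at which both models display their qualitative behaviour clearly
(reconstruction gap inside lesions, near-binary discriminator maps).

## Known limitations

- Full-scale (90×90×54×64, 500-epoch) training is out of reach on CPU;
  the architecture scales but has only been exercised at phantom scale.
- The phantom's lesions are far easier than infiltrating glioma; absolute
  Dice/AUC values here do not transfer to clinical data.
- The uniform-noise "range" convention, CSF inclusion in brain statistics,
  residual-map normalization before fixed thresholding, and joint vs.
  sequential RecDisc training are genuinely underdetermined design points;
  each is implemented with the documented default plus a config switch.
- Out-of-mask voxels are NaN in restricted maps; writers store them as NaN
  in NIfTI, which downstream tools must tolerate.
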