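# Methods

## Problem and model

Deep-learning classifiers for prostate MR images are starved of annotated
data: lesions are rare, labelling is expensive, and class balance is poor.
One remedy is to synthesise extra training images with a generative
adversarial network (GAN). This package implements such a model — a
least-squares GAN whose discriminator is a capsule network — together with
a quantitative metric for judging how close generated images are to real
ones.

### Adversarial objective

The classic GAN solves the minimax game

    min_G max_D  V(D, G) = E_{x~p_data}[log D(x)] + E_{z~p_z}[log(1 − D(G(z)))].

At the optimum for a fixed generator, D*(x) = p_data(x) / (p_data(x) + p_g(x)),
and the generator cost reduces to

    C(G) = −log 4 + 2 · JSD(p_data ‖ p_g),

so training minimises a Jensen–Shannon divergence — a quantity whose
gradients vanish when the two distributions barely overlap. The package
therefore trains with least-squares targets instead:

    V(D) = ½ E[(D(x) − 1)²] + ½ E[D(G(z))²],      V(G) = ½ E[(D(G(z)) − 1)²].

Squared-error penalties grow with distance from the target code, so samples
that are confidently classified but far from the real data manifold still
produce gradient. The sigmoid-cross-entropy objective is retained as a
baseline (`loss_mode="cross_entropy"`), and the closed-form fixed-point
identities above are used as exact test oracles on discrete toy densities.

### Generator

A DCGAN-style deconvolution stack: latent vector (default 100-dimensional,
Gaussian prior with a uniform option) → fully connected projection to a
4×4 seed feature map → one stride-2 transposed convolution (5×5 kernels)
per doubling of resolution → Tanh output in [−1, 1]. Batch normalisation
and ReLU follow every hidden layer; the output layer has neither. Images
convert to file range via y = (x + 1) · 127.5 (and back by the inverse
map); the midpoint 127.5 rounds half-up to 128 when writing 8-bit PNGs.
Channel widths halve per stage from a configurable seed width
(1024 at 64×64; 64 at the 16×16 desk scale).

### Capsule discriminator

A capsule is a vector-valued group of neurons: the vector's length encodes
the probability that an entity is present, its orientation encodes pose.
The discriminator is:

1. **Low-level features** — a conventional convolution (9×9 kernels at
   32–64 px, 5×5 at 16 px; large kernels buy a large shallow receptive
   field), then batch norm and LeakyReLU. The leaky slope is 0.2; the
   negative branch is multiplicative (0.2·x). A `literal` mode dividing by
   the slope is available for completeness but amplifies negatives
   five-fold, which destabilises training.
2. **Primary capsules** — a second convolution (stride 2) whose output
   channels are reshaped into 8-dimensional capsule vectors and squashed:
   v = (‖s‖²/(1+‖s‖²)) · s/‖s‖, which preserves direction and maps norms
   into [0, 1).
3. **Dynamic routing** to a single 16-dimensional output capsule
   (real/fake is one entity, so one capsule suffices). Routing by
   agreement runs r = 3 iterations: couplings c = softmax(b) over output
   capsules, weighted sum s_j = Σ_i c_ij û_ij of the prediction vectors
   û_ij = W_ij u_i, activation v_j, and agreement update b_ij += û_ij·v_j.
   Logits b start at zero; W is initialised N(0, 0.01²). The routing
   activation defaults to LeakyReLU (squash at every routing step tends to
   produce artifacts in the generated images); `activation_mode="squash"`
   restores the classic network. With all-zero predictions the agreement
   dot products vanish and the logits simply stay at zero — documented,
   not special-cased.
4. **Score** — the L2 norm of the output capsule. Nonnegative, and
   bounded below 1 only in squash mode.

The margin loss
L_k = T_k max(0, m⁺−‖v_k‖)² + λ(1−T_k) max(0, ‖v_k‖−m⁻)²
(m⁺ = 0.9, m⁻ = 0.1, λ = 0.5) is implemented for the classic multi-class
capsule head but is not used by the adversarial objective, which scores
the single capsule with least squares.

A plain strided-convolution discriminator (`discriminator="conv"`) provides
the DCGAN/LSGAN baseline for comparison runs.

### Numerical backbone

The networks run on a small reverse-mode automatic-differentiation tape
over numpy arrays written for this package (`capgan._tensor`,
`capgan._layers`): elementwise ops, matmul, im2col convolutions, transposed
convolutions, fused batch norm and LeakyReLU, and Adam. Training uses
float32; analysis paths and gradient checks use float64. All gradients are
verified against central finite differences in the test suite, end to end
through routing and both losses. Optimisation uses Adam with learning rate 2·10⁻⁴ and β₁ = 0.5 (the usual
DCGAN convention), one discriminator update per generator update, batch
size 64 (32 at desk scale).

A master seed fans out through named substreams to parameter
initialisation, latent sampling and data shuffling, so runs are exactly
reproducible; checkpoints carry parameters, optimiser moments and RNG
states and resume bit-identically. Non-finite losses abort with a
diagnostic snapshot.

## Quality metric

Inception-based scores (IS, FID) lean on a natural-image classifier that
transfers poorly to medical images. The package instead measures
distributional similarity through a task-specific classifier:

1. extract HOG (9 orientations, 8×8-pixel cells, 2×2-cell blocks, L2 block
   norm; 4-px cells at 16×16 so more than one block exists) and LBP
   (8 neighbours, radius 1, uniform rotation-invariant patterns,
   histogram normalised to 1) features and concatenate them, HOG first;
2. train an RBF-kernel SVM (C = 1) with calibrated probability outputs on
   standardized features of *real* images;
3. push equal-sized real and generated sets through the classifier and
   histogram the positive-class probabilities on 10 equal-width bins over
   [0, 1], adding 1/(10·n_bins) to every bin before renormalising so the
   histogram is strictly positive;
4. report KL(real ‖ generated) = Σ_i P_i ln(P_i/Q_i) in nats.

Identical sets score exactly 0; same-distribution synthetic samples score
< 0.05 at n = 500. The divergence is asymmetric; real plays P by
convention.

**Classifier task.** With a two-class real corpus (e.g. malignant/benign
lesions) the SVM is trained on those labels. A one-class corpus (the
phantom experiments) offers no such task, so the packaged studies train a
*realism* classifier: real images against unstructured negatives
(pixel-shuffled, constant-gray, and uniform-noise images derived from a
disjoint real subset). This protocol was selected by a validity check
independent of any GAN: the metric must grade increasingly corrupted real
images monotonically. Near-miss negatives (mildly corrupted real images)
failed that check: even light corruption immediately saturated the metric.

**Known limitation.** When the realism task is cleanly separable, real
images concentrate in the top probability bin, and any generated set with
no mass there scores near the smoothing ceiling ln(1/ε) ≈ 4.2 nats;
comparisons between two clearly-unreal sets therefore have small margins.
Absolute values also depend on the bin count and smoothing, so only
relative comparisons under one binning are meaningful.

## Synthetic data

No external imaging data is downloaded; all fixtures are generated:

* **Phantoms** — nested elliptical shells (default 3) with per-shell
  intensity levels (200/130/80), randomly posed and jittered
  (deformation ±8 % of the shell axes), plus Gaussian pixel noise
  (σ = 8 gray levels). They emulate simulated T1-weighted head slices:
  a bright outer rim with nested tissue-like plateaus. They do *not*
  reproduce cortical folding, partial-volume edges, bias fields or scanner
  noise statistics, so passing tests demonstrate the machinery works and
  learns simple anatomy-like structure — not clinical-grade synthesis.
* **Lesion patches** — two classes with a 75:250 malignant:benign
  imbalance (the skew typical of prostate mp-MRI lesion corpora) on a smooth tissue background (Gaussian-filtered noise around
  gray level 110). Benign lesions are smooth hypointense disks
  (radius 5–7 px, −45 gray levels); malignant lesions add boundary
  irregularity (cosine lobes, amplitude 0.35·s), +2 px radius and internal
  speckle (σ = 22·s), all scaled by a separability knob s ∈ [0, 1]. At
  s = 0 the two labels are drawn from one distribution (classifier AUC ≈
  0.5); at s = 1 HOG+LBP+SVM reaches ≥ 0.9 held-out accuracy.
* **Pipeline operators** — axial slicing of 3-D volumes; 35×35 ROI crops
  centred on the lesion (centre at patch pixel (17, 17); reflect padding
  handles borders); augmentation
  by rotation ±15°, translation ±3 px, scaling 0.9–1.1 and additive noise
  σ = 5 (mild, to preserve anatomy); dataset expansion; stratified 80/20
  splitting with per-class round-to-nearest. "Expand 20×" keeps the
  originals (n·(k+1): 260 → 5,460), while the phantoms' "10-fold"
  expansion does not (1,400 → 14,000); both conventions are exercised per
  experiment via the expansion helpers.

## Desk-scale study sizes

The packaged studies run on one CPU: 16×16 phantoms, 1,000 training
images, 2,000 generator updates, batch 32, generator seed width 64 and a
16-filter first discriminator layer. The 64×64 defaults use the full-size
architecture (4×4×1024 seed map, four deconvolution stages, 9×9
discriminator kernels) and train the same way, only slower. Under the desk
conditions, KL(real ‖ trained generator) beats KL(real ‖ untrained
generator) in 5 of 5 seeds (the acceptance suite requires ≥ 4/5), while
both values sit near the metric's saturation ceiling — at this scale the
generator learns coarse shell structure, not fine texture.

## Design choices on genuinely open points

* The leaky rectifier defaults to the conventional multiplicative slope;
  a literal mode dividing by the slope exists for completeness (see above).
* Latent prior: Gaussian by default, uniform available — both are common
  choices and the architecture is agnostic to them.
* Training length is counted in generator-update steps (the common usage
  for small image corpora, where "epochs" is ambiguous); the default of
  50,000 steps is fully configurable.
* Routing iterations are unstated; r = 3 follows the original
  capsule-network convention.
* Exact parameter counts are not an interface contract: filter counts and
  strides are config-driven, so totals vary with the chosen geometry.
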