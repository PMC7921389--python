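# Methods

## Overview

`lungpatterns` re-implements, end to end and on synthetic data, an
unsupervised pipeline for discovering lung-tissue *pattern-clusters* and their
latent traits from paired inspiration/expiration CT:

1. **Preprocessing** — raw HU volumes are rescaled to a tissue fraction
   (0 = air, 1 = tissue) using per-subject trachea/aorta medians; the
   expiratory deformation enters as the voxel-wise Jacobian determinant of a
   displacement field.  The two channels share the [0, 1] scale, which keeps
   gradient-based training well conditioned.
2. **CAE-FC** — a dual-channel 3D convolutional autoencoder with a
   feature-constructor (FC) head learns a length-E nonnegative embedding per
   32³-voxel region of interest (ROI); the FC keeps the k largest activations
   and assigns each ROI the index of its maximal activation
   (its pattern-cluster).
3. **Histograms** — after training, sliding windows over each subject's lung
   are assigned to clusters and counted into a per-subject length-E proportion
   vector.
4. **EFA** — exploratory factor analysis of the cohort's histograms: the
   factor count comes from Horn's parallel analysis, extraction is
   principal-axis factoring, rotation is oblique promax, and per-subject
   factor scores use the regression (Thurstone) method.
5. **Statistics** — factor scores predict continuous outcomes (OLS, AIC model
   selection over the embedding-count grid, forward selection with partial
   F-tests), separate severity groups (Welch's ANOVA + Games–Howell), and
   classify a binary outcome (logistic regression with ROC/AUC).

Everything is evaluated on synthetic cohorts with known ground truth; no
clinical data ships with or is downloaded by the package.

## The synthetic cohort model

Each subject has an ellipsoidal "lung" inscribed in the volume, partitioned
into Voronoi blobs.  Each blob carries one of C texture classes; a class is a
stationary Gaussian random field with its own HU mean/SD, smoothing scale,
Jacobian mean/SD, and an additive RV offset (small offsets emulate air
trapping, large positive offsets normally deflating tissue).  Subject-level
mixing is latent-trait-driven: with loading matrix **L** (classes × factors)
and factor scores **f** ~ N(0, I), blob classes are drawn from
softmax(**L f**).  The continuous outcome is **β·f** + Gaussian noise with
SD = 0.3·‖β‖ (a synthetic spirometry analogue); the binary outcome is a
Bernoulli draw through a logistic link on the same linear predictor (a
synthetic exacerbation analogue).

Key generator defaults and why:

- **4 classes** anchored to clinically meaningful HU regimes: emphysema-like
  (−960 ± 15 HU, Jacobian 0.95, RV offset +30 — stays below the −856 HU
  air-trapping threshold at expiration), fSAD-like (−880 ± 20, J 0.85,
  +10), normal (−820 ± 35, J 0.55, +120) and dense/fibrotic-like
  (−650 ± 50, J 0.75, +80).  PRM ground truth is therefore controllable.
- **Loading matrix** [[1.5,0],[−1.5,0],[0,1.5],[0,−1.5]]: factor 0 trades the
  two low-attenuation classes, factor 1 the two denser classes.
- **32 blobs per subject**: realized class fractions then track the softmax
  proportions with relative sampling error ~1/√32 ≈ 18%.  A blob-level
  Monte Carlo of the *information ceiling* (regressing the outcome on true
  fractions) shows this is the regime in which two factors are recoverable
  from composition at cohort sizes of tens of subjects; with 4–8 blobs the
  blob-sampling noise alone caps the achievable R² near 0.4 and parallel
  analysis misses the second factor in half the cohorts.
- **Displacement field**: u = (u_z, 0, 0) with u_z the cumulative sum of
  (J − 1)·voxel-spacing along z.  Because the resulting Jacobian matrix is
  triangular, det(I + ∇u) reproduces the class-driven Jacobian field (up to
  the half-voxel smoothing of the central-difference stencil), so the
  pipeline genuinely computes its Jacobian channel from a displacement field
  rather than being handed the answer.

What the generator does **not** emulate: anatomy (airway trees, lobes,
pleura), scanner noise and reconstruction kernels, registration error, and
spatially correlated disease progression.  Passing tests therefore
demonstrate that the pipeline recovers planted compositional latent structure
under controlled conditions — not that it would recover clinical phenotypes.

## CAE-FC architecture and training

- Encoder: one stride-2 3×3×3 convolution per halving (default channels
  16-32-64 on full-size ROIs; the benchmark experiments use 8-16-32), ReLU
  between stages, final convolution to E channels, global average pooling.
- **Embedding normalisation**: the pooled E-vector is batch-normalised per
  channel (learnable affine, shift initialised at 0.1) and passed through a
  final ReLU.  This step is load-bearing: without it, training with a top-k
  gate collapses every ROI onto a single pattern-cluster, because one channel
  can dominate the argmax for all inputs while still reducing reconstruction
  error through its magnitude.  Standardising each channel across the batch
  makes the argmax winner input-dependent.  At evaluation time running
  statistics are used, so batched and single-ROI evaluation agree exactly.
- FC gate: hard top-k, default and benchmark k = 1 (the decoder reconstructs
  from the single strongest activation; `gate_keep_k` is config-exposed).
  Gradients are straight-through.  Ties break to the lowest index everywhere.
- Decoder: nearest-neighbour ×2 upsampling + 3×3×3 convolution per stage,
  mirroring the encoder, linear output over both channels.
- Loss: mean squared reconstruction error over both channels (they share the
  [0, 1] scale by construction).  Optimiser Adam (default lr 1e-3; the
  benchmark uses 3e-3 for its short 5-epoch schedule).  An optional
  mean-activation entropy-balancing term (`balance_weight`) exists but is off
  by default — the embedding normalisation already prevents collapse.
- All layers are plain numpy with explicit backpropagation, validated by
  finite-difference gradient checks.  Determinism holds within one
  process/BLAS; cross-platform bitwise equality is not promised.

## EFA details

- Parallel analysis compares the leading eigenvalues of the observed
  correlation matrix against the 95th percentile (default, 100 replicates) of
  eigenvalues of same-shape standard-normal data, rank by rank, and retains
  the leading run that exceeds the threshold.
- Principal-axis factoring iterates communalities from squared-multiple-
  correlation starts (tolerance 1e-6; the pipeline allows 2000 iterations —
  compositional data converge slowly).  Heywood cases are clipped to 1 with a
  warning.
- Promax (power 4) on a Kaiser-normalised varimax solution; each factor is
  sign-flipped so its largest-|loading| entry is positive.
- Histogram proportions sum to one, so their correlation matrix is exactly
  singular.  Squared-multiple-correlation starts and the regression score
  weights therefore use rank-truncated pseudo-inverses (a warning is emitted
  when the condition number exceeds 1e8); this is the stabilised equivalent
  of ridge regularisation.
- Constant columns (clusters never used) are carried with zero loadings and
  zero score weight rather than dropped from the interface.

## Statistical layer

- AIC uses the Gaussian form n·ln(RSS/n) + 2p with p = k + 2 (intercept and
  error variance counted); only differences are meaningful.
- Forward selection adds the largest-partial-F candidate and stops when its
  p-value exceeds α = 0.05 or the fit is numerically perfect.  Note two
  structural facts, verified by simulation and matching theory: (i) the
  AIC-minimal subset over all candidates includes a spurious predictor with
  probability ≈ 0.157 per noise variable (AIC's penalty of 2 ↔ a χ²₁ > 2
  test), so the α = 0.05 forward path agrees with the exhaustive best-AIC
  subset in only ~72% of strong-signal replicates — the two rules genuinely
  differ; and (ii) a null problem with m candidates ends with an empty
  selection with probability ≈ 0.95^m, so the null benchmark uses m = 2.
- Welch's ANOVA uses the heteroscedastic F with Welch–Satterthwaite df.  At
  k = 2 it equals the squared Welch t exactly; for k ≥ 3 the correction
  factor b > 1 means it does not reduce to the classic F at finite n.
- Games–Howell p-values come from the studentized-range distribution
  (scipy's numerical implementation), with the pair-specific
  Welch–Satterthwaite df and the full group count k.
- "Bi-serial" correlation is implemented as point-biserial (Pearson on 0/1
  coding), flagged in the result; latent-normal biserial is not implemented.
- Logistic regression is Newton–Raphson (tolerance 1e-8) with a small ridge
  on the Hessian; complete separation is detected, warned about, and the
  evaluation still produced.  AUC uses the midrank Mann–Whitney formula,
  which equals trapezoidal integration of the swept ROC exactly.

## The benchmark experiments (what `scripts/acceptance.py` runs)

The end-to-end experiment uses 40 training + 20 held-out subjects with 48³
volumes, the 4-class/2-factor generator above, E = 8 pattern-clusters, and 5
training epochs, repeated over 5 seeds.  Problem sizes were chosen so the
whole benchmark completes in well under an hour on one CPU: 12 random
training ROIs per subject, a 24-voxel sliding-window overlap (stride 8 → 27
windows per 48³ subject; at the default 16-voxel overlap such small volumes
would yield only 8 windows, too few for a stable 8-bin histogram), and
encoder channels 8-16-32.

A structural caveat discovered while building the benchmark and worth
stating plainly: with 48³ volumes and 32³ windows, *every* sliding window
contains the volume's centre, so the per-subject histogram is estimated from
heavily overlapping, strongly correlated windows.  Replacing the CAE with
idealised assigners (ground-truth majority labels, or k-means on the raw
patches) caps the held-out R² of the factor-score regression at roughly
0.3–0.4 at this geometry, against an information ceiling of ~0.66 when
regressing on the true class fractions directly.  The measured CAE-FC chain
lands below that oracle band.  Larger volumes relative to the window (as in
real CT, where thousands of quasi-independent windows exist per lung) remove
this bottleneck; the 48³ setting is a deliberately small smoke-scale cohort.

The other benchmark quantities are: cluster/class adjusted Rand index next
to a k-means baseline on the same flattened patches; exact-count agreement
of the PRM classifier with a per-voxel brute-force relabeling plus a
hand-enumerated 4-voxel case (25/25/50); analytic and oracle checks of the
Jacobian determinant; the Welch-t² identity; the studentized-range critical
value q(0.05, k=3, df=10) = 3.88; forward-selection recovery rates; and
planted-loading EFA recovery (parallel-analysis retention, Tucker
congruence, score correlation).

## Known limitations

- The FC is a top-k gate; the original network's multi-layer feature
  constructor is not publicly specified, so this is the simplest mechanism
  with the stated behaviour (suppress small activations; cluster by the
  greatest), not a claim about the original.
- Extraction/rotation/scoring choices (PAF, promax, regression scores) are
  standard defaults; alternatives (minres, oblimin, Bartlett) are not
  implemented.
- Training at the scale of hundreds of thousands of ROIs is out of scope;
  the numpy implementation is sized for cohorts of tens of subjects.
- `resample_isotropic` uses the node-convention grid (original nodes are
  reproduced when the spacing divides evenly); masks resample
  nearest-neighbour.
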