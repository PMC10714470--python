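# Methods

## Model

The classifier is a fully connected feed-forward network on 1200-bin
fingerprint vectors: layers 1200 → 300 → 225 → 100 → n_classes with ReLU
activations and 25% dropout after the first and second hidden layers
(training only). It is made Bayesian by variational inference: every weight
and bias w is given an independent Gaussian posterior q(w) = N(μ, σ²) with
σ = softplus(ρ) (strictly positive by construction), against an isotropic
standard-normal prior. Training minimises the negative evidence lower bound

  L = E_q[−log p(y | x, w)] + β · KL(q ‖ N(0, 1)),

estimated with the reparameterization trick (w = μ + σ·ε, ε ~ N(0,1), one
weight sample per minibatch by default) and the closed-form per-parameter KL
ln(1/σ) + (σ² + μ²)/2 − 1/2. Gradients are computed analytically
(hand-written reverse mode; d/dμ = ∂L/∂w, d/dρ = ∂L/∂w · ε · sigmoid(ρ))
and verified against central finite differences in the test suite at 1e-4
relative tolerance. The optimiser is Adam.

Assumptions worth stating: posteriors are fully factorised (mean-field), the
prior is a single unit Gaussian rather than a scale mixture (keeps the KL
closed-form; the screening behaviour does not hinge on prior heaviness), and
dropout acts purely as a training regulariser — at inference time the only
stochasticity is weight sampling, so the repeated-inference spread is a
clean epistemic signal rather than a mixture of two noise sources.

### KL weighting

The data term is the batch-*mean* cross-entropy, so the ELBO-consistent KL
weight is β = 1/n_train: multiplying the per-batch objective by the batch
size recovers sum-cross-entropy + KL/num_batches, i.e. exactly one full KL
charged per epoch. Weighting the KL by 1/num_batches against a batch-mean
likelihood would overcount it by the batch size (64×); in that regime the
posterior is dragged to the prior and the network never leaves chance
accuracy. β is exposed in `TrainConfig` for experiments.

### Defaults

| parameter | default | rationale |
|---|---|---|
| epochs | 50 | loss and validation accuracy plateau well before this on the default corpus |
| batch size | 64 | standard; 88 minibatches per epoch at n_train = 5600 |
| learning rate | 1e-3 | Adam default regime |
| MC samples/step | 1 | standard Bayes-by-Backprop practice; gradient noise is averaged by Adam |
| init | μ ~ N(0, 0.1²)/√fan_in, ρ = −3 (σ ≈ 0.0486) | near-deterministic start, posterior widens only where the data allow |
| dropout | 0.25, hidden layers 1–2 | over-fitting guard on 451k-parameter nets trained from few source spectra |

## Preprocessing

Raw spectra are two-column (wavenumber cm⁻¹, intensity) traces. They are
linearly interpolated onto 1200 bin centers at half-integers
(2600.5 … 3799.5 cm⁻¹, 1 cm⁻¹ step — half-integer centers make the bin
count exactly 1200 over the 1200 cm⁻¹ window); grid bins outside a
spectrum's support take its minimum intensity (baseline) to avoid artificial
edges; the result is z-scored with the population (divide-by-N) standard
deviation. Interpolation happens before z-scoring. Consequences used as
test invariants: preprocessing is idempotent on the standard grid and exactly
invariant to affine intensity transforms a·I + b (a > 0). Constant spectra
and spectra not overlapping the window are errors, never silently zeroed.

## Synthetic fingerprint library

No laboratory monosaccharide spectra are distributed with the package, so a
generator emulates their statistical structure. Each class is a template of
Gaussian bands (center, FWHM, amplitude ≤ 1, peak-height normalised). The
known classes behave like stereoisomers: they share a backbone of 10
identical bands and differ in 3 distinguishing bands whose centers are
displaced between classes by up to ±20 cm⁻¹ (pairwise displaced-band
separation ≥ ~9 cm⁻¹, comparable to one bandwidth). FWHMs are drawn from
U(5, 15) cm⁻¹ at standard resolution; the low-resolution instrument variant
multiplies every FWHM by 3 ("broader and less resolved"). Out-of-distribution
molecules come in two difficulties: at least 3 from an entirely foreign band
family (unrelated centers), the rest as perturbed members of the known
family — every backbone band shifted by 20–45 cm⁻¹ and rescaled, plus two
extra bands — emulating disaccharides or sulfated variants that carry the
same chemical motif. The variant displacement floor deliberately exceeds
the ±10 cm⁻¹ calibration-shift fluctuation modelled by the augmentation:
an "OOD molecule" whose bands sit within the instrument's day-to-day
variability of a known class would not be a different molecule but a repeat
measurement, and no screening rule could (or should) reject it. Renders add ±5% uniform amplitude jitter so replicate
measurements differ; 8 standard-resolution replicates per known class stand
in for the ~8 laboratory spectra per class of a realistic reference set.

What the generator does **not** emulate: real band positions or intensities
of any actual sugar, anomer equilibria (folded into replicate jitter),
correlated baseline drifts, detector nonlinearity, or Lorentzian/Voigt wings
(Gaussian lineshapes throughout — IRMPD bands are unresolved envelopes and
the classifier contract does not depend on the wing shape). Passing tests
therefore demonstrate that the *method* — augmentation, variational
training, IPR screening — works on a library with the right separability
structure, not that any real monosaccharide would be classified with these
accuracies.

## Augmentation

Four perturbations, applied in a fixed order, then preprocessing:

1. wavenumber shift, U(−10, +10) cm⁻¹ (calibration drift);
2. downsampling: intensities rebinned at an integer width drawn uniformly
   from {1..5} cm⁻¹ (mean within bin) and re-interpolated to 1 cm⁻¹
   (fast-scan acquisition); the factor is integer because rebinning widths
   are bin-multiples;
3. linear amplitude modulation: gain 1 + s·(ν − 3200)/600 with
   s ~ U(−0.10, +0.10), i.e. ±s at the window edges (laser-power drift);
4. additive Gaussian white noise with σ ~ U(0, 0.05) × the spectrum's peak
   signal (per-spectrum maximum).

Noise comes after rebinning so it is not smoothed away; normalisation is
last. `AugmentationParams` itself accepts magnitudes beyond the training
ranges (e.g. a demonstration perturbation with 10% noise, 5% amplitude
modulation, downsampling 2 and a +9 cm⁻¹ shift is constructible); the closed
sampling ranges are owned by `AugmentationConfig`. The identity parameter set (0, 0, 1, 0) reproduces plain preprocessing
bit-exactly. Every draw is recorded in a per-spectrum ledger
(id, class, noise_frac, amp_slope, downsample, shift, split) which the
sweep analysis later bins. The default corpus is 2000 augmentations per
class from uniformly chosen source replicates, shuffled and split 70/30
stratified by class (stratification keeps the split balanced; the ledger
records it).

## Uncertainty screening

`predict_distribution` runs T = 200 stochastic forward passes (weights
resampled each pass, dropout off) and summarises each class's probability by
its mean and 5th/95th percentiles under the linear-interpolation percentile
definition (the definition matters at O(1/T) and is fixed for
reproducibility). The acceptance rule is strict: the argmax class's
IPR = p95 − p5 must be strictly below the threshold, default 0.35.

Metrics on an annotated mixture: precision = accepted ∧ in-distribution ∧
correctly classified / accepted (the compound definition — a sample accepted
but misclassified counts against precision); TPR = in-distribution accepted ∧
correct / in-distribution; FPR = OOD accepted / OOD. Zero-denominator ratios
are NaN with an explicit warning.

## Baseline comparators

Random forest (300 trees, unlimited depth) and gradient-boosted trees
(300 rounds, depth 6, learning rate 0.1) via scikit-learn and XGBoost, on
byte-identical vectors and splits. The forest's discrimination analogue
treats the per-tree class votes as the inference ensemble (mean vote
fraction, 5–95 IPR across trees); boosted trees have no comparable ensemble
of members, so their rule accepts iff max class probability > 1 − threshold
(pseudo-IPR = 1 − max probability). These analogues are this package's own
constructions for putting all three methods on one operating axis.

## Problem sizes and numerical choices

The default study (also what `scripts/acceptance.py` runs) uses the full
corpus scale — 8000 training/validation vectors, an 8000-vector broadened
test set, a 1300-vector discrimination mixture from 12 originals
(5 known renders over 3 classes + 7 OOD) — with 50 training epochs and
T = 200 inferences; it completes in minutes on one CPU. Unit and property
tests run on reduced corpora (tens to hundreds of vectors) chosen so each
property is still exercised, with one full-scale run shared by the
end-to-end test module. Other fixed choices: softmax is computed with max
subtraction; probabilities are clipped at 1e-300 before the log; the
near-deterministic limit in tests sets ρ = −40 (σ ≈ 4e-18); checkpoint
format is JSON metadata + a single `.npz` of named float arrays, validated
against the declared shapes on load.

## Known limitations

- The generator's separability is benign for classification: at the default
  settings the trained network reaches perfect validation accuracy and
  essentially zero in-distribution IPR. Harder libraries (closer
  distinguishing bands, lower amplitudes, more shared structure) can be
  configured through `LibrarySpec`.
- Screening precision on the default mixture is typically in the 97–100%
  range depending on the library seed: the foreign-family OOD are rejected
  without exception, but an occasional *near-family variant* render lands
  close enough to a known class's learned invariances to be accepted with a
  confident (low-IPR) prediction. Epistemic uncertainty from mean-field
  posteriors is a practical but not infallible OOD detector for molecules
  that differ from a trained class by little more than the modelled
  experimental fluctuations.
- Mean-field Gaussian posteriors understate weight correlations; the IPR is
  a practical epistemic proxy, not a calibrated posterior probability.
- The screening threshold 0.35 is a fixed operating point; no
  threshold-tuning or conformal machinery is included.
- Training is CPU-bound NumPy; it is sized for the default study, not for
  architecture search or much larger corpora.
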