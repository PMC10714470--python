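# glycofp

Bayesian neural-network classification of gas-phase IR fingerprints of
monosaccharides, with epistemic-uncertainty screening of unknown spectra.

## The problem

Mass spectrometry augmented with infrared action spectroscopy (MS–IR)
resolves carbohydrate isomers that have identical masses: each mass-selected
ion is interrogated with a tunable IR laser, and the wavelength-dependent
fragmentation yield traces out a vibrational fingerprint in the
2600–3800 cm⁻¹ window. Stereoisomeric monosaccharides (e.g. glucosamine,
galactosamine, mannosamine) share most of their bands and differ in only a
few — so assigning a fingerprint to a class, and knowing when a spectrum
belongs to *none* of the referenced classes (a disaccharide, a sulfated
variant, a contaminant), is the analytical bottleneck for automated,
high-throughput carbohydrate sequencing.

`glycofp` addresses both halves of that problem for spectroscopists and
glycomics pipeline builders:

- a **variational (Bayesian) multilayer perceptron** — every weight carries a
  Gaussian posterior N(μ, σ²), σ = softplus(ρ), trained by Bayes-by-Backprop
  against a standard-normal prior on z-scored, 1200-bin fingerprint vectors
  (architecture 1200 → 300 → 225 → 100 → n_classes, ReLU, 25% dropout after
  the first two hidden layers, cross-entropy likelihood);
- **repeated-inference uncertainty screening** — each spectrum is classified
  T = 200 times with freshly sampled weights; the 5–95 interpercentile range
  (IPR) of the winning class's probability measures epistemic uncertainty,
  and a prediction is accepted only when IPR < 0.35. In-distribution spectra
  give sharp distributions (IPR ≈ 0); out-of-distribution spectra give broad
  ones and are flagged for manual review instead of being mislabelled;
- an **experimental-fluctuation augmentation** scheme (white noise up to 5%
  of peak signal, ±10% linear amplitude drift, 1–5 cm⁻¹ rebinning, ±10 cm⁻¹
  calibration shift) that expands a handful of measured spectra into
  thousands of training examples;
- a **synthetic fingerprint generator** (Gaussian band templates with a
  shared stereoisomer backbone, foreign-family and near-family OOD
  molecules, a broadened low-resolution instrument variant) so the whole
  pipeline runs and is tested without access to laboratory spectra;
- **tree-ensemble comparators** (random forest, gradient-boosted trees) with
  an IPR analogue built from the across-tree vote distribution.

## Worked example

```python
import numpy as np
from glycofp import (LibrarySpec, AugmentationConfig, TrainConfig, make_library,
                     render, build_corpus, BayesianSpectrumClassifier,
                     predict_distribution, discriminate, preprocess)

library = make_library(LibrarySpec(seed=0))          # 4 known + 7 OOD classes
known = [t for t in library if not t.name.startswith("OOD:")]
rng = np.random.default_rng(0)
replicates = {t.name: [render(t, rng=rng) for _ in range(8)] for t in known}
corpus = build_corpus(replicates, AugmentationConfig(n_per_class=500, seed=1))
fit = BayesianSpectrumClassifier.from_corpus(corpus).fit(TrainConfig(epochs=30, seed=2))
print(fit.summary())
```

```text
Bayesian spectrum classifier (Bayes-by-Backprop)
====================================================
layers:           1200 -> 300 -> 225 -> 100 -> 4
parameters:       451029 (mu, rho pairs: 902058)
classes:          monoA, monoB, monoC, monoD
epochs trained:   30
final loss:       617.4512
final KL (nats):  864359.0
val accuracy:     1.0000 (mean-weight passes)
posterior scale per layer (mean sigma):
  layer 0: weights 0.0914  biases 0.0913
  ...
```

The fitted posterior classifies every held-out validation vector correctly.
Screening one known and one contaminant spectrum with 200 repeated
inferences:

```python
contaminant = [t for t in library if t.name.startswith("OOD:")][0]
x = preprocess(render(contaminant, rng=rng)).values
dist = predict_distribution(fit.model, x, T=200, rng=np.random.default_rng(3))[0]
decision = discriminate(dist, threshold=0.35)
```

```text
contaminant spectrum -> predicted monoB (mean prob 0.60, IPR 0.96) -> accepted: False
known monoC spectrum -> predicted monoC (mean prob 1.00, IPR 0.00) -> accepted: True
```

The contaminant is *not* assigned to a class even though some inferences give
it a high probability: its prediction distribution is broad (IPR 0.96 ≫ 0.35),
which is precisely the epistemic signature of a molecule the model has never
seen. The known spectrum is accepted with an essentially zero IPR.

## Command line

```sh
glycofp generate-library --seed 1 --out lib/          # render templates + manifest
glycofp augment --library lib/ --out corpus/          # 8000-vector corpus + ledger
glycofp train --data corpus/ --out ckpt/              # Bayes-by-Backprop fit
glycofp predict --model ckpt/ --input lib/ --out pred.csv
glycofp evaluate --predictions pred.csv --ledger corpus/ledger.csv --out sweep/
glycofp benchmark --seed 1 --out report/              # + RF / XGBoost comparison
glycofp run-all --seed 1 --out report/                # full pipeline, summary JSON
```

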