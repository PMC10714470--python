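"""Experimental-fluctuation data augmentation.

Training corpora are built by perturbing source spectra with the four
fluctuation sources seen between repeat IRMPD measurements:

1. *wavenumber shift* — day-to-day laser calibration drift, up to +/-10 cm^-1
   per spectrum;
2. *downsampling* — faster acquisition at degraded resolution: intensities are
   rebinned at an integer bin width of 1-5 cm^-1 (mean within bin) and
   re-interpolated onto the 1 cm^-1 grid;
3. *linear amplitude modulation* — slow laser-power drift across the scan,
   a linear gain ramp spanning +/-10% across the spectral range;
4. *additive Gaussian white noise* — shot-to-shot noise with a standard
   deviation of 0-5% of the spectrum's peak signal.

Perturbations are applied in that order (shift, downsample, modulate, noise)
so the noise is not smoothed away by rebinning, and normalization
(`preprocess`) always comes last.  `build_corpus` draws one parameter set per
synthetic spectrum, records it in a ledger (so accuracy can later be studied
as a function of each parameter), shuffles, and splits 70/30 stratified by
class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .spectra import GRID_MAX, GRID_MIN, Spectrum, SpectrumVector, preprocess

__all__ = [
    "AugmentationParams",
    "AugmentationConfig",
    "Corpus",
    "sample_params",
    "apply",
    "build_corpus",
]


@dataclasses.dataclass(frozen=True)
class AugmentationParams:
    """The four perturbation magnitudes drawn for one synthetic spectrum."""

    noise_frac: float  # noise std as a fraction of peak signal
    amp_slope: float  # linear gain at the range edges (+s at high end, -s at low)
    downsample: int  # rebin width in cm^-1
    shift: float  # wavenumber shift in cm^-1

    def __post_init__(self) -> None:
        if not np.isfinite([self.noise_frac, self.amp_slope, self.shift]).all():
            raise ValueError("non-finite augmentation parameter")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if int(self.downsample) != self.downsample or self.downsample < 1:
            raise ValueError("downsample must be an integer >= 1")


@dataclasses.dataclass
class AugmentationConfig:
    """Sampling ranges for the four perturbations plus corpus-level settings.

    Defaults are the study conditions: noise 0-5% of peak signal, amplitude
    modulation +/-10%, integer downsampling 1-5, shift +/-10 cm^-1; 2000
    synthetic spectra per class with a 70/30 train/validation split.
    """

    noise_range: tuple[float, float] = (0.0, 0.05)
    amp_slope_range: tuple[float, float] = (-0.10, 0.10)
    downsample_range: tuple[int, int] = (1, 5)
    shift_range: tuple[float, float] = (-10.0, 10.0)
    n_per_class: int = 2000
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def sample_params(config: AugmentationConfig, rng: np.random.Generator) -> AugmentationParams:
    """Draw one parameter set: all four marginals uniform and independent."""
    return AugmentationParams(
        noise_frac=float(rng.uniform(*config.noise_range)),
        amp_slope=float(rng.uniform(*config.amp_slope_range)),
        downsample=int(rng.integers(config.downsample_range[0], config.downsample_range[1] + 1)),
        shift=float(rng.uniform(*config.shift_range)),
    )


def _rebin(wavenumbers: np.ndarray, intensities: np.ndarray, width: int
           ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-rebin onto bins of ``width`` cm^-1, then back to the 1 cm^-1 grid."""
    grid = np.arange(np.ceil(wavenumbers[0]), np.floor(wavenumbers[-1]) + 1.0)
    y = np.interp(grid, wavenumbers, intensities)
    n_bins = len(grid) // width
    if n_bins < 2:
        raise ValueError("spectrum too short to rebin at this width")
    trimmed = y[: n_bins * width].reshape(n_bins, width)
    centers = grid[: n_bins * width].reshape(n_bins, width).mean(axis=1)
    coarse = trimmed.mean(axis=1)
    return grid, np.interp(grid, centers, coarse)


def apply(
    spec: Spectrum, params: AugmentationParams, rng: np.random.Generator
) -> SpectrumVector:
    """Perturb a spectrum and preprocess it to a network input vector.

    Order: wavenumber shift; rebin/re-interpolate at the downsampling width;
    linear amplitude modulation centered on the 3200 cm^-1 grid midpoint;
    additive white noise scaled to the peak signal; then `preprocess`.  With
    the identity parameters (0, 0, 1, 0) the result equals ``preprocess(spec)``
    exactly.
    """
    wn = spec.wavenumbers + params.shift
    inten = spec.intensities
    if params.downsample > 1:
        wn, inten = _rebin(wn, inten, int(params.downsample))
    mid = 0.5 * (GRID_MIN + GRID_MAX)
    half_range = 0.5 * (GRID_MAX - GRID_MIN)
    inten = inten * (1.0 + params.amp_slope * (wn - mid) / half_range)
    if params.noise_frac > 0:
        inten = inten + rng.normal(0.0, params.noise_frac * float(np.max(inten)), size=len(inten))
    else:
        rng.normal(0.0, 1.0, size=len(inten))  # keep the rng stream aligned
    meta = dict(spec.meta)
    meta["augmentation"] = dataclasses.asdict(params)
    perturbed = Spectrum(wn, inten, label=spec.label, meta=meta)
    return preprocess(perturbed)


@dataclasses.dataclass
class Corpus:
    """Augmented, shuffled, split corpus plus its parameter ledger.

    The ledger has one row per synthetic spectrum (columns: id, class,
    noise_frac, amp_slope, downsample, shift, split) and is the basis of the
    accuracy-vs-parameter analysis.
    """

    train: list[SpectrumVector]
    val: list[SpectrumVector]
    ledger: pd.DataFrame

    def __len__(self) -> int:
        return len(self.train) + len(self.val)

    def arrays(self, classes: list[str] | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """(X_train, y_train, X_val, y_val, class_names) as dense arrays."""
        if classes is None:
            classes = sorted({v.label for v in self.train})
        index = {c: i for i, c in enumerate(classes)}
        xt = np.stack([v.values for v in self.train])
        yt = np.array([index[v.label] for v in self.train])
        xv = np.stack([v.values for v in self.val])
        yv = np.array([index[v.label] for v in self.val])
        return xt, yt, xv, yv, classes


def build_corpus(
    spectra_by_class: dict[str, list[Spectrum]], config: AugmentationConfig
) -> Corpus:
    """Augment every class to ``n_per_class`` vectors, shuffle and split.

    Each synthetic spectrum starts from a uniformly chosen source spectrum of
    its class and one freshly sampled `AugmentationParams` (recorded in the
    ledger).  The split is 70/30 (``train_fraction``) stratified by class and
    the whole construction is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    vectors: list[SpectrumVector] = []
    rows: list[dict] = []
    for cls in sorted(spectra_by_class):
        sources = spectra_by_class[cls]
        if not sources:
            raise ValueError(f"class {cls!r} has no source spectra")
        for i in range(config.n_per_class):
            src = sources[int(rng.integers(len(sources)))]
            params = sample_params(config, rng)
            vec = apply(src, params, rng)
            vec.label = cls
            sid = f"{cls}-{i:05d}"
            vec.meta["id"] = sid
            vectors.append(vec)
            rows.append({"id": sid, "class": cls, **dataclasses.asdict(params)})
    ledger = pd.DataFrame(rows)

    # stratified split, then a global shuffle of each side
    split = np.empty(len(vectors), dtype=object)
    for cls in sorted(spectra_by_class):
        idx = np.flatnonzero(ledger["class"].to_numpy() == cls)
        idx = rng.permutation(idx)
        n_train = round(config.train_fraction * len(idx))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "val"
    ledger["split"] = split
    train_idx = rng.permutation(np.flatnonzero(split == "train"))
    val_idx = rng.permutation(np.flatnonzero(split == "val"))
    return Corpus(
        train=[vectors[i] for i in train_idx],
        val=[vectors[i] for i in val_idx],
        ledger=ledger,
    )
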