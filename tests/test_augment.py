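"""Augmentation perturbations, parameter sampling and corpus construction."""

import numpy as np
import pytest
from scipy import stats

from glycofp.augment import (
    AugmentationConfig,
    AugmentationParams,
    apply,
    build_corpus,
    sample_params,
)
from glycofp.spectra import Spectrum, grid_centers, preprocess
from glycofp.synth import FOUR_LN2


def _narrow_peak(center=3000.0, fwhm=6.0):
    x = np.arange(2600.0, 3801.0)
    y = np.exp(-FOUR_LN2 * (x - center) ** 2 / fwhm**2) + 0.01
    return Spectrum(x, y)


class TestSampleParams:
    def test_uniform_marginals_over_8000_draws(self):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(0)
        draws = [sample_params(cfg, rng) for _ in range(8000)]
        crit = 1.628 / np.sqrt(8000)  # 1% KS critical value, large-n
        for field, (lo, hi) in (
            ("noise_frac", cfg.noise_range),
            ("amp_slope", cfg.amp_slope_range),
            ("shift", cfg.shift_range),
        ):
            vals = np.array([getattr(p, field) for p in draws])
            d = stats.kstest(vals, stats.uniform(lo, hi - lo).cdf).statistic
            assert d < crit, field
        counts = np.bincount([p.downsample for p in draws], minlength=6)[1:]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_seeded_rng_replays_identically(self):
        cfg = AugmentationConfig()
        a = [sample_params(cfg, np.random.default_rng(42)) for _ in range(5)]
        b = [sample_params(cfg, np.random.default_rng(42)) for _ in range(5)]
        assert a == b

    def test_downsample_support(self):
        rng = np.random.default_rng(1)
        vals = {sample_params(AugmentationConfig(), rng).downsample for _ in range(10_000)}
        assert vals == {1, 2, 3, 4, 5}


class TestApply:
    def test_identity_params_equal_preprocess_exactly(self):
        spec = _narrow_peak()
        out = apply(spec, AugmentationParams(0.0, 0.0, 1, 0.0), np.random.default_rng(0))
        ref = preprocess(spec)
        np.testing.assert_array_equal(out.values, ref.values)

    def test_wavenumber_shift_moves_peak(self):
        # narrow peak at 3000 with +9 cm^-1 shift lands at 3009
        out = apply(_narrow_peak(), AugmentationParams(0.0, 0.0, 1, 9.0),
                    np.random.default_rng(0))
        peak = grid_centers()[np.argmax(out.values)]
        assert abs(peak - 3009.0) <= 0.5

    def test_downsampling_broadens_peak_and_matches_bruteforce(self):
        spec = _narrow_peak(fwhm=4.0)
        rng = np.random.default_rng(0)
        out1 = apply(spec, AugmentationParams(0.0, 0.0, 1, 0.0), rng)
        out4 = apply(spec, AugmentationParams(0.0, 0.0, 4, 0.0), rng)

        def fwhm(values):
            # half-max crossings by linear interpolation on the grid
            g = grid_centers()
            half = (values.max() + values.min()) / 2.0
            above = np.flatnonzero(values >= half)
            lo, hi = above[0], above[-1]
            left = np.interp(half, values[lo - 1 : lo + 1], g[lo - 1 : lo + 1])
            right = np.interp(half, values[hi + 1 : hi - 1 : -1], g[hi + 1 : hi - 1 : -1])
            return right - left

        assert fwhm(out4.values) > fwhm(out1.values) + 0.5

        # independent brute-force rebinning oracle on the toy peak
        grid = np.arange(2600.0, 3801.0)
        y = np.interp(grid, spec.wavenumbers, spec.intensities)
        n_bins = len(grid) // 4
        coarse = y[: 4 * n_bins].reshape(n_bins, 4).mean(axis=1)
        centers = grid[: 4 * n_bins].reshape(n_bins, 4).mean(axis=1)
        expected = preprocess(Spectrum(grid, np.interp(grid, centers, coarse)))
        np.testing.assert_allclose(out4.values, expected.values, atol=1e-9)

    def test_amplitude_modulation_tilts_spectrum(self):
        # flat-ish two-peak spectrum: +10% slope boosts the high-wavenumber peak
        x = np.arange(2600.0, 3801.0)
        y = (np.exp(-((x - 2800.0) ** 2) / 50.0) + np.exp(-((x - 3600.0) ** 2) / 50.0)) + 0.01
        spec = Spectrum(x, y)
        out = apply(spec, AugmentationParams(0.0, 0.10, 1, 0.0), np.random.default_rng(0))
        ref = preprocess(spec)
        g = grid_centers()
        lo_peak = np.argmin(np.abs(g - 2800.0))
        hi_peak = np.argmin(np.abs(g - 3600.0))
        assert (out.values[hi_peak] - out.values[lo_peak]) > (
            ref.values[hi_peak] - ref.values[lo_peak]
        )

    def test_noise_scales_with_peak_signal(self):
        spec = _narrow_peak()
        ref = preprocess(spec)
        out = apply(spec, AugmentationParams(0.05, 0.0, 1, 0.0), np.random.default_rng(3))
        assert not np.allclose(out.values, ref.values, atol=1e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AugmentationParams(-0.1, 0.0, 1, 0.0)
        with pytest.raises(ValueError):
            AugmentationParams(0.0, 0.0, 0, 0.0)


class TestBuildCorpus:
    def test_sizes_split_and_ledger(self, small_corpus):
        n_classes, n_per = 4, 120
        assert len(small_corpus) == n_classes * n_per
        counts = small_corpus.ledger["class"].value_counts()
        assert (counts == n_per).all()
        assert len(small_corpus.train) == round(0.70 * n_classes * n_per)
        assert len(small_corpus.val) == n_classes * n_per - len(small_corpus.train)

    def test_split_is_a_stratified_permutation(self, small_corpus):
        ids_train = {v.meta["id"] for v in small_corpus.train}
        ids_val = {v.meta["id"] for v in small_corpus.val}
        assert not (ids_train & ids_val)
        assert ids_train | ids_val == set(small_corpus.ledger["id"])
        per_class_train = small_corpus.ledger.query("split == 'train'")["class"].value_counts()
        assert (per_class_train == 84).all()  # 70% of 120, per class

    def test_every_vector_is_zscored(self, small_corpus):
        for vec in small_corpus.train[:50] + small_corpus.val[:50]:
            assert abs(vec.values.mean()) < 1e-6
            assert abs(vec.values.std() - 1.0) < 1e-6

    def test_deterministic_given_seed(self, small_library):
        from glycofp.synth import render

        known = [t for t in small_library if not t.name.startswith("OOD:")][:2]
        cfg = AugmentationConfig(n_per_class=20, seed=9)

        def build():
            rng = np.random.default_rng(4)
            by_class = {t.name: [render(t, rng=rng) for _ in range(2)] for t in known}
            return build_corpus(by_class, cfg)

        a, b = build(), build()
        assert a.ledger.equals(b.ledger)
        np.testing.assert_array_equal(a.train[0].values, b.train[0].values)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no source spectra"):
            build_corpus({"x": []}, AugmentationConfig(n_per_class=5))
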