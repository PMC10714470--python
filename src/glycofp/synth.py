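"""Synthetic IR fingerprint library.

Real monosaccharide IRMPD fingerprints are not publicly deposited, so this
module generates a surrogate library with the same statistical structure:
a handful of "known" classes that behave like stereoisomers (many shared
vibrational bands, a few distinguishing ones), plus out-of-distribution (OOD)
molecules — some from an unrelated band family (think paracetamol next to
hexosamines) and some that are perturbed relatives of the known family
(disaccharide- or sulfation-like variants).

Every template is a list of Gaussian bands (center, FWHM, amplitude) in the
2600-3800 cm^-1 window; `render` evaluates it on a uniform grid, optionally
with multiplicatively broadened bands to emulate a lower-resolution
instrument, and with a small per-render amplitude jitter so repeated renders
differ like replicate measurements.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectra import GRID_MAX, GRID_MIN, Spectrum

__all__ = ["ClassTemplate", "LibrarySpec", "make_library", "render", "FOUR_LN2"]

FOUR_LN2 = 4.0 * np.log(2.0)

_MARGIN = 50.0  # keep band centers this far inside the grid edges


@dataclasses.dataclass
class ClassTemplate:
    """Ground-truth band list for one molecular class.

    peaks: sequence of (center cm^-1, fwhm cm^-1, amplitude) with centers in
    [2600, 3800], fwhm in [3, 60] and amplitudes in (0, 1].  Templates sharing
    a ``family_id`` share a common band backbone.
    """

    name: str
    peaks: list[tuple[float, float, float]]
    family_id: int = 0

    def __post_init__(self) -> None:
        if len(self.peaks) < 5:
            raise ValueError(f"{self.name}: need >= 5 peaks, got {len(self.peaks)}")
        for c, w, a in self.peaks:
            if not (GRID_MIN <= c <= GRID_MAX):
                raise ValueError(f"{self.name}: peak center {c:g} outside grid")
            if not (3.0 <= w <= 60.0):
                raise ValueError(f"{self.name}: fwhm {w:g} outside [3, 60]")
            if not (0.0 < a <= 1.0):
                raise ValueError(f"{self.name}: amplitude {a:g} outside (0, 1]")

    @property
    def centers(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])


@dataclasses.dataclass
class LibrarySpec:
    """Configuration of the synthetic class library.

    Defaults emulate the study layout: 4 known stereoisomer-like classes and
    7 OOD molecules.  Knowns share ``n_shared_peaks`` identical bands and
    differ in ``n_distinct_peaks`` bands whose centers are displaced between
    classes by up to ``distinct_shift`` cm^-1.  The library is a deterministic
    function of ``seed``.
    """

    n_known: int = 4
    n_ood: int = 7
    seed: int = 0
    n_shared_peaks: int = 10
    n_distinct_peaks: int = 3
    distinct_shift: float = 20.0
    fwhm_range: tuple[float, float] = (5.0, 15.0)

    def __post_init__(self) -> None:
        if self.n_known < 2:
            raise ValueError("n_known must be >= 2")
        if self.n_ood < 0:
            raise ValueError("n_ood must be >= 0")
        if self.n_shared_peaks + self.n_distinct_peaks < 5:
            raise ValueError("templates need at least 5 peaks in total")


def _spaced_centers(rng: np.random.Generator, n: int, min_sep: float) -> np.ndarray:
    """Draw n band centers with minimum separation, well inside the grid."""
    lo, hi = GRID_MIN + _MARGIN, GRID_MAX - _MARGIN
    slack = (hi - lo) - (n - 1) * min_sep
    if slack <= 0:
        raise ValueError(f"cannot place {n} peaks with separation {min_sep:g} in range")
    # uniform order statistics on the slack, then re-inflate the minimum gaps
    return lo + np.sort(rng.uniform(0.0, slack, size=n)) + np.arange(n) * min_sep


def _draw_family(rng: np.random.Generator, spec: LibrarySpec, n_members: int, *,
                 family_id: int, names: list[str]) -> list[ClassTemplate]:
    """One family: a shared backbone plus per-member displaced distinct bands."""
    n_total = spec.n_shared_peaks + spec.n_distinct_peaks
    centers = _spaced_centers(rng, n_total, min_sep=3.0 * spec.distinct_shift)
    which_distinct = rng.choice(n_total, size=spec.n_distinct_peaks, replace=False)
    lo_w, hi_w = spec.fwhm_range
    fwhm = rng.uniform(lo_w, hi_w, size=n_total)
    amp = rng.uniform(0.3, 1.0, size=n_total)

    members: list[ClassTemplate] = []
    for k in range(n_members):
        peaks = []
        for j in range(n_total):
            if j in which_distinct:
                # distinguishing band: class-specific center displacement and
                # amplitude, as stereoisomers shift a few bands
                offsets = np.linspace(-spec.distinct_shift, spec.distinct_shift,
                                      max(n_members, 2))
                c = centers[j] + offsets[k % len(offsets)] + rng.uniform(-2.0, 2.0)
                a = float(np.clip(rng.uniform(0.5, 1.0), 0.0, 1.0))
                w = rng.uniform(lo_w, hi_w)
            else:
                c, w, a = centers[j], fwhm[j], amp[j]
            peaks.append((float(c), float(w), float(a)))
        members.append(ClassTemplate(names[k], peaks, family_id=family_id))
    return members


def make_library(spec: LibrarySpec) -> list[ClassTemplate]:
    """Build the full template library: known classes first, then OOD.

    Known classes share a backbone of ``n_shared_peaks`` identical bands.  At
    least 3 OOD templates come from an entirely different band family; the
    remaining OOD templates are perturbed members of the known family (all
    bands shifted and rescaled, with extra bands added), emulating
    disaccharides or sulfated variants.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    known_names = [f"mono{chr(65 + k)}" for k in range(spec.n_known)]
    known = _draw_family(rng, spec, spec.n_known, family_id=0, names=known_names)

    templates = list(known)
    if spec.n_ood > 0:
        n_foreign = min(spec.n_ood, max(3, (spec.n_ood + 1) // 2))
        foreign_names = [f"OOD:foreign{i}" for i in range(n_foreign)]
        templates += _draw_family(rng, spec, n_foreign, family_id=1, names=foreign_names)

        # near-family OOD: every band of the known backbone displaced and
        # rescaled, plus two new bands (a larger molecule carrying the same
        # motif).  Displacements start above the +-10 cm^-1 calibration-shift
        # fluctuation so these are different molecules, not repeat measurements.
        base = known[0]
        for i in range(spec.n_ood - n_foreign):
            peaks = []
            for c, w, a in base.peaks:
                c2 = c + rng.choice([-1.0, 1.0]) * rng.uniform(20.0, 45.0)
                w2 = float(np.clip(w * rng.uniform(0.8, 1.5), 3.0, 60.0))
                a2 = float(np.clip(a * rng.uniform(0.6, 1.4), 0.05, 1.0))
                peaks.append((float(np.clip(c2, GRID_MIN + 5, GRID_MAX - 5)), w2, a2))
            for _ in range(2):
                peaks.append((
                    float(rng.uniform(GRID_MIN + _MARGIN, GRID_MAX - _MARGIN)),
                    float(rng.uniform(*spec.fwhm_range)),
                    float(rng.uniform(0.4, 1.0)),
                ))
            templates.append(ClassTemplate(f"OOD:variant{i}", peaks, family_id=0))
    return templates


def render(
    template: ClassTemplate,
    broadening: float = 1.0,
    grid_step: float = 1.0,
    rng: np.random.Generator | None = None,
    amp_jitter: float = 0.05,
) -> Spectrum:
    """Render a template as a Spectrum on a uniform grid over 2600-3800 cm^-1.

    Bands are Gaussian lineshapes with peak height equal to the band amplitude
    and FWHM scaled by ``broadening`` (>= 1; e.g. 3 for the low-resolution
    instrument variant).  If ``rng`` is given, each band amplitude is jittered
    uniformly by +/- ``amp_jitter`` so repeated renders differ like replicate
    measurements; without an rng the render is exact.
    """
    if broadening < 1.0:
        raise ValueError("broadening must be >= 1")
    x = np.arange(GRID_MIN, GRID_MAX + grid_step / 2.0, grid_step)
    y = np.zeros_like(x)
    for c, w, a in template.peaks:
        if rng is not None and amp_jitter > 0:
            a = a * (1.0 + rng.uniform(-amp_jitter, amp_jitter))
        weff = w * broadening
        y += a * np.exp(-FOUR_LN2 * (x - c) ** 2 / weff**2)
    return Spectrum(
        x, y, label=template.name,
        meta={"template": template.name, "broadening": broadening},
    )
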