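"""Spectrum containers, file I/O and preprocessing onto the network grid.

A gas-phase IR fingerprint is stored as a raw (wavenumber, intensity) trace
(`Spectrum`).  Before classification every trace is linearly interpolated onto
a fixed 1200-bin grid covering 2600-3800 cm^-1 (1 cm^-1 step, bin centers at
half-integers) and z-scored, giving a `SpectrumVector` — the only object the
classifiers ever see.

Dataset bookkeeping (which file carries which label, which acquisition
variant, which train/val/test split) lives in a `Manifest`, a thin wrapper
around a four-column CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GRID_MIN",
    "GRID_MAX",
    "N_BINS",
    "grid_centers",
    "Spectrum",
    "SpectrumVector",
    "Manifest",
    "SpectrumParseError",
    "DegenerateSpectrumError",
    "SpectrumRangeError",
    "ManifestError",
    "read_spectrum",
    "write_spectrum",
    "preprocess",
    "read_manifest",
    "write_manifest",
]

GRID_MIN = 2600.0
GRID_MAX = 3800.0
N_BINS = 1200

VALID_SPLITS = ("train", "val", "test", "none")
VALID_DATASETS = ("1", "2", "3", "synthetic")


def grid_centers() -> np.ndarray:
    """Bin centers of the fixed network grid: 2600.5, 2601.5, ..., 3799.5."""
    return GRID_MIN + 0.5 + np.arange(N_BINS, dtype=float)


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; names the offending line."""


class DegenerateSpectrumError(ValueError):
    """Raised for constant-intensity spectra (z-score undefined)."""


class SpectrumRangeError(ValueError):
    """Raised when a spectrum does not overlap the 2600-3800 cm^-1 grid."""


class ManifestError(ValueError):
    """Raised for structurally invalid manifests."""


@dataclasses.dataclass
class Spectrum:
    """Raw IR fingerprint: intensities of vibrational resonances vs. wavenumber.

    Parameters
    ----------
    wavenumbers : array, cm^-1, strictly increasing, length >= 2
    intensities : array, arbitrary units, same length, finite
    label : class name, ``"OOD:<name>"`` for out-of-distribution species, or
        ``"unknown"``
    meta : free-form provenance (template id, augmentation params, instrument
        variant, ...)
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = "unknown"
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclasses.dataclass
class SpectrumVector:
    """Preprocessed network input: 1200 z-scored intensities on the fixed grid.

    Values have mean 0 and population standard deviation 1 (enforced to 1e-6);
    the wavenumber axis is implicit (`grid_centers`).
    """

    values: np.ndarray
    label: str = "unknown"
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"expected shape ({N_BINS},), got {self.values.shape}")
        if abs(float(self.values.mean())) > 1e-6:
            raise ValueError("vector is not z-scored: mean != 0")
        if abs(float(self.values.std()) - 1.0) > 1e-6:
            raise ValueError("vector is not z-scored: population std != 1")

    def as_spectrum(self) -> Spectrum:
        """Reinterpret the vector as a Spectrum on the standard grid."""
        return Spectrum(grid_centers(), self.values.copy(), self.label, dict(self.meta))


def read_spectrum(path: str | Path, label: str = "unknown") -> Spectrum:
    """Read a two-column (wavenumber, intensity) text file.

    Comma-, tab- or whitespace-delimited; ``#`` comments and a single optional
    header line are allowed.  Rows are sorted by increasing wavenumber;
    duplicate wavenumbers are an error.
    """
    path = Path(path)
    wn: list[float] = []
    inten: list[float] = []
    saw_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = [f for f in line.replace(",", " ").split() if f]
            if len(fields) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                w, v = float(fields[0]), float(fields[1])
            except ValueError:
                if not saw_data:
                    # tolerate one header line before any data
                    saw_data = True
                    continue
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            if not (np.isfinite(w) and np.isfinite(v)):
                raise SpectrumParseError(f"{path}:{lineno}: non-finite value")
            wn.append(w)
            inten.append(v)
            saw_data = True
    if len(wn) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data points")
    order = np.argsort(wn, kind="stable")
    wn_arr = np.asarray(wn)[order]
    if np.any(np.diff(wn_arr) == 0):
        dup = wn_arr[np.flatnonzero(np.diff(wn_arr) == 0)[0]]
        raise SpectrumParseError(f"{path}: duplicate wavenumber {dup:g}")
    return Spectrum(wn_arr, np.asarray(inten)[order], label=label, meta={"source": str(path)})


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV with a commented header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# wavenumber_cm-1,intensity\n")
        for w, v in zip(spec.wavenumbers, spec.intensities):
            fh.write(f"{w:.6f},{v:.10g}\n")


def preprocess(spec: Spectrum) -> SpectrumVector:
    """Interpolate a spectrum onto the 1200-bin grid and z-score it.

    Linear interpolation onto the bin centers 2600.5 ... 3799.5 cm^-1; grid
    bins outside the spectrum's support are filled with the spectrum's
    baseline (its minimum intensity) before z-scoring.  The z-score uses the
    population (divide-by-N) standard deviation.

    Raises
    ------
    SpectrumRangeError
        if the spectrum does not overlap [2600, 3800] cm^-1.
    DegenerateSpectrumError
        if the gridded intensities are constant.
    """
    if spec.wavenumbers[-1] < GRID_MIN or spec.wavenumbers[0] > GRID_MAX:
        raise SpectrumRangeError(
            f"spectrum [{spec.wavenumbers[0]:g}, {spec.wavenumbers[-1]:g}] cm^-1 "
            f"does not overlap the [{GRID_MIN:g}, {GRID_MAX:g}] grid"
        )
    baseline = float(spec.intensities.min())
    gridded = np.interp(
        grid_centers(), spec.wavenumbers, spec.intensities, left=baseline, right=baseline
    )
    sd = float(gridded.std())
    if sd == 0.0:
        raise DegenerateSpectrumError("constant spectrum: z-score undefined")
    values = (gridded - gridded.mean()) / sd
    return SpectrumVector(values, label=spec.label, meta=dict(spec.meta))


class Manifest:
    """Dataset manifest: rows of (path, label, dataset, split).

    ``dataset`` is one of {1, 2, 3, synthetic} and ``split`` one of
    {train, val, test, none}.  Paths are unique and labels non-empty.
    """

    COLUMNS = ("path", "label", "dataset", "split")

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=list(self.COLUMNS))
        frame = frame.reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
        frame = frame[list(self.COLUMNS)].astype(str)
        for col, valid in (("split", VALID_SPLITS), ("dataset", VALID_DATASETS)):
            bad = sorted(set(frame[col]) - set(valid))
            if bad:
                hint = ""
                if col == "split" and "validation" in bad:
                    hint = ' (did you mean "val"?)'
                raise ManifestError(f"unknown {col} value(s) {bad}{hint}; valid: {valid}")
        if frame["path"].duplicated().any():
            dup = frame.loc[frame["path"].duplicated(), "path"].iloc[0]
            raise ManifestError(f"duplicate path {dup!r}")
        if (frame["label"].str.len() == 0).any():
            raise ManifestError("empty label")
        self.frame = frame

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "Manifest":
        return cls(pd.DataFrame(list(rows), columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Manifest) and self.frame.equals(other.frame)


def read_manifest(path: str | Path) -> Manifest:
    """Read a manifest CSV (header: path,label,dataset,split)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return Manifest()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Manifest(frame)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.frame.to_csv(path, index=False)
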