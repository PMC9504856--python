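"""Domain types and the preprocessing chain for NIR spectra.

The package represents every spectrum on a shared, uniformly spaced
wavenumber grid (default 10,000-4000 cm^-1 at 2 cm^-1).  Diffuse-reflectance
measurements are converted to apparent absorbance A = log10(1/R), brought to
a common baseline by a linear offset correction (subtraction of the minimum
over a chosen region), and, for most analyses, averaged to one spectrum per
polymer and water-concentration level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: water mass fractions of the reference experimental design (w/w)
DESIGN_WATER_FRACTIONS = (0.0, 0.01, 0.03, 0.05, 0.07, 0.10)

MODE_REFLECTANCE = "reflectance"
MODE_ABSORBANCE = "absorbance"


class SpectraError(ValueError):
    """Raised for invalid spectra, grids or metadata."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly monotone, uniformly spaced wavenumber axis in cm^-1.

    Stored ascending regardless of acquisition order.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectraError("grid needs at least two wavenumbers")
        if np.any(v <= 0):
            raise SpectraError("wavenumbers must be positive")
        d = np.diff(v)
        if np.any(d <= 0):
            raise SpectraError("grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise SpectraError("grid spacing must be uniform")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, lo: float = 4000.0, hi: float = 10000.0,
                step: float = 2.0) -> "WavenumberGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, WavenumberGrid)
                and self.values.shape == other.values.shape
                and np.array_equal(self.values, other.values))

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber``; exact ties go to
        the lower wavenumber, matching discrete instrument sampling."""
        v = self.values
        i = int(np.searchsorted(v, wavenumber))
        if i == 0:
            return 0
        if i >= v.size:
            return v.size - 1
        # tie -> lower wavenumber (index i-1)
        return i - 1 if wavenumber - v[i - 1] <= v[i] - wavenumber else i

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices with lo <= wavenumber <= hi (bounds in either order)."""
        lo, hi = min(lo, hi), max(lo, hi)
        idx = np.nonzero((self.values >= lo) & (self.values <= hi))[0]
        if idx.size == 0:
            raise SpectraError(
                f"window [{lo}, {hi}] cm^-1 does not overlap the grid")
        return idx


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: matrix label, water content and replicate ids."""

    polymer: str
    water_fraction: float
    preparation: int = 1
    measurement: int = 1
    sample_id: str = ""
    n_averaged: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.water_fraction <= 1.0:
            raise SpectraError(
                f"water_fraction {self.water_fraction} outside [0, 1]")
        if self.preparation < 1 or self.measurement < 1:
            raise SpectraError("preparation/measurement are 1-based")
        if not self.sample_id:
            object.__setattr__(
                self, "sample_id",
                f"{self.polymer}_w{self.water_fraction:g}"
                f"_p{self.preparation}_m{self.measurement}")


@dataclass
class Spectrum:
    """One spectrum on a grid, in reflectance or absorbance mode."""

    grid: WavenumberGrid
    intensity: np.ndarray
    mode: str = MODE_ABSORBANCE
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.grid),):
            raise SpectraError(
                f"intensity length {y.size} != grid length {len(self.grid)}")
        if np.any(~np.isfinite(y)):
            raise SpectraError("intensity contains non-finite values")
        if self.mode not in (MODE_REFLECTANCE, MODE_ABSORBANCE):
            raise SpectraError(f"unknown mode {self.mode!r}")
        if self.mode == MODE_REFLECTANCE and (np.any(y <= 0) or np.any(y > 1)):
            raise SpectraError("reflectance values must lie in (0, 1]")
        self.intensity = y

    def value_at(self, wavenumber: float) -> float:
        return float(self.intensity[self.grid.nearest_index(wavenumber)])

    def to_absorbance(self) -> "Spectrum":
        if self.mode == MODE_ABSORBANCE:
            return self
        return Spectrum(self.grid, reflectance_to_absorbance(self.intensity),
                        MODE_ABSORBANCE, self.meta)


@dataclass
class SpectraSet:
    """Aligned spectra matrix (n_samples x n_points) plus per-row metadata.

    The universal currency passed between all analysis stages.
    """

    grid: WavenumberGrid
    matrix: np.ndarray
    meta: list[SampleMeta]
    mode: str = MODE_ABSORBANCE

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.grid):
            raise SpectraError("matrix shape does not match the grid")
        if len(self.meta) != m.shape[0]:
            raise SpectraError("metadata length != number of rows")
        if np.any(~np.isfinite(m)):
            raise SpectraError("matrix contains non-finite values")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise SpectraError("empty spectra list")
        grid = spectra[0].grid
        modes = {s.mode for s in spectra}
        if len(modes) > 1:
            raise SpectraError("mixed reflectance/absorbance spectra")
        for s in spectra[1:]:
            if s.grid != grid:
                raise SpectraError("spectra do not share one grid")
        return cls(grid, np.vstack([s.intensity for s in spectra]),
                   [s.meta or SampleMeta("?", 0.0) for s in spectra],
                   spectra[0].mode)

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i].copy(), self.mode,
                        self.meta[i])

    def select(self, predicate: Callable[[SampleMeta], bool]) -> "SpectraSet":
        idx = [i for i, m in enumerate(self.meta) if predicate(m)]
        if not idx:
            raise SpectraError("selection matched no samples")
        return SpectraSet(self.grid, self.matrix[idx],
                          [self.meta[i] for i in idx], self.mode)

    def water_fractions(self) -> np.ndarray:
        return np.array([m.water_fraction for m in self.meta])

    def ensure_absorbance(self) -> "SpectraSet":
        """Auto-convert reflectance sets on entry to any analysis."""
        if self.mode == MODE_ABSORBANCE:
            return self
        logger.info("converting %d reflectance spectra to absorbance",
                    len(self))
        return SpectraSet(self.grid,
                          reflectance_to_absorbance(self.matrix),
                          self.meta, MODE_ABSORBANCE)


# ---------------------------------------------------------------------------
# preprocessing operations


def reflectance_to_absorbance(values: np.ndarray) -> np.ndarray:
    """Apparent absorbance A = log10(1/R), elementwise."""
    v = np.asarray(values, dtype=float)
    bad = np.nonzero(v <= 0)
    if bad[0].size:
        raise SpectraError(
            f"reflectance <= 0 at index {tuple(b[0] for b in bad)}")
    return -np.log10(v)


def absorbance_to_reflectance(values: np.ndarray) -> np.ndarray:
    return np.power(10.0, -np.asarray(values, dtype=float))


def linear_offset_correct(spectrum: Spectrum | SpectraSet,
                          region: tuple[float, float] | None = None):
    """Subtract each spectrum's minimum over ``region`` (default: full grid).

    Brings all spectra to a common zero baseline while leaving every
    point-to-point intensity difference untouched; idempotent.
    """
    grid = spectrum.grid
    idx = (np.arange(len(grid)) if region is None
           else grid.window_indices(*region))
    if isinstance(spectrum, SpectraSet):
        s = spectrum.ensure_absorbance()
        out = s.matrix - s.matrix[:, idx].min(axis=1, keepdims=True)
        return SpectraSet(grid, out, list(s.meta), MODE_ABSORBANCE)
    s = spectrum.to_absorbance()
    return Spectrum(grid, s.intensity - s.intensity[idx].min(),
                    MODE_ABSORBANCE, s.meta)


def snv(spectrum: Spectrum | SpectraSet):
    """Standard Normal Variate: per spectrum, mean 0 / sample sd 1."""
    def _snv_rows(m: np.ndarray) -> np.ndarray:
        sd = m.std(axis=1, ddof=1)
        if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
            raise SpectraError("SNV of a constant spectrum is undefined")
        return (m - m.mean(axis=1, keepdims=True)) / sd[:, None]

    if isinstance(spectrum, SpectraSet):
        s = spectrum.ensure_absorbance()
        return SpectraSet(s.grid, _snv_rows(s.matrix), list(s.meta), s.mode)
    s = spectrum.to_absorbance()
    return Spectrum(s.grid, _snv_rows(s.intensity[None, :])[0], s.mode,
                    s.meta)


def average_group(spectra: SpectraSet,
                  keys: Sequence[str] = ("polymer", "water_fraction"),
                  ) -> SpectraSet:
    """Average to one spectrum per unique combination of metadata ``keys``.

    Groups keep their first-seen order; the result's metadata carries the
    group keys and the member count in ``n_averaged``.
    """
    if len(spectra) == 0:
        raise SpectraError("empty spectra set")
    for k in keys:
        if not hasattr(spectra.meta[0], k):
            raise SpectraError(f"unknown metadata key {k!r}")
    s = spectra.ensure_absorbance()
    groups: dict[tuple, list[int]] = {}
    for i, m in enumerate(s.meta):
        groups.setdefault(tuple(getattr(m, k) for k in keys), []).append(i)
    rows, metas = [], []
    for key, idx in groups.items():
        rows.append(s.matrix[idx].mean(axis=0))
        proto = s.meta[idx[0]]
        kv = dict(zip(keys, key))
        metas.append(SampleMeta(
            polymer=kv.get("polymer", proto.polymer),
            water_fraction=kv.get("water_fraction", proto.water_fraction),
            preparation=kv.get("preparation", 1),
            measurement=kv.get("measurement", 1),
            sample_id="avg_" + "_".join(f"{k}={v:g}" if isinstance(v, float)
                                        else f"{k}={v}"
                                        for k, v in kv.items()),
            n_averaged=len(idx)))
    return SpectraSet(s.grid, np.vstack(rows), metas, s.mode)
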