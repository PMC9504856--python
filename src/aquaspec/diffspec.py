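"""Anchored difference spectroscopy and water-band shift tracking.

To resolve the water component of a polymer-water mixture spectrum, the
pure-polymer spectrum is scaled so that it matches the mixture at a
polymer-specific reference wavenumber (a band where water does not absorb)
and subtracted; the polymer component is resolved analogously by scaling
the pure-water spectrum at the combination-band maximum of water,
5180 cm^-1.  The scaling factor is the plain intensity ratio
``f = mixture(anchor) / reference(anchor)`` read at the nearest grid
point.  Negative difference values are physically meaningful (intensity
lost to hydrogen bonding) and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpectraError, SpectraSet, Spectrum, WavenumberGrid

#: per-polymer reference wavenumbers (cm^-1) for scaling the pure-polymer
#: spectrum, and the water combination-band maximum used for the reverse.
DEFAULT_ANCHORS: dict[str, float] = {
    "PTFE": 5944.0, "PP": 5796.0, "PS": 5952.0, "PVC": 5828.0,
    "POM": 5968.0, "PA": 5828.0, "lignin": 5964.0, "chitin": 5800.0,
    "cellulose": 5604.0,
}
WATER_ANCHOR = 5180.0


@dataclass
class DifferenceResult:
    """Resolved component line shapes per concentration level."""

    component: str                      # "water" or "polymer"
    anchor_wavenumber: float
    grid: WavenumberGrid
    water_fractions: np.ndarray         # ascending
    scaling_factors: np.ndarray         # one f >= 0 per concentration
    differences: np.ndarray             # n_conc x n_points

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.differences[i].copy())


def scaling_factor(mixture: Spectrum, reference: Spectrum,
                   anchor: float) -> float:
    """Intensity ratio mixture/reference at the grid point nearest anchor."""
    if mixture.grid != reference.grid:
        raise SpectraError("mixture and reference are on different grids")
    g = mixture.grid.values
    if not g[0] <= anchor <= g[-1]:
        raise SpectraError(f"anchor {anchor} cm^-1 outside the grid span")
    i = mixture.grid.nearest_index(anchor)
    ref = reference.intensity[i]
    if ref <= 0:
        raise SpectraError(
            f"reference intensity {ref:g} at {g[i]:g} cm^-1 is not positive")
    return float(mixture.intensity[i] / ref)


def component_difference(mixture: Spectrum, reference: Spectrum,
                         f: float) -> Spectrum:
    """Pointwise ``mixture - f * reference`` (negative values preserved)."""
    if mixture.grid != reference.grid:
        raise SpectraError("mixture and reference are on different grids")
    return Spectrum(mixture.grid,
                    mixture.intensity - f * reference.intensity,
                    mixture.mode, mixture.meta)


def _series(spectra: SpectraSet, reference: Spectrum, anchor: float,
            component: str) -> DifferenceResult:
    s = spectra.ensure_absorbance()
    ref = reference.to_absorbance()
    order = np.argsort(s.water_fractions(), kind="stable")
    fracs, factors, diffs = [], [], []
    for i in order:
        mix = s.row(int(i))
        f = scaling_factor(mix, ref, anchor)
        diffs.append(component_difference(mix, ref, f).intensity)
        factors.append(f)
        fracs.append(mix.meta.water_fraction)
    return DifferenceResult(component, anchor, s.grid,
                            np.asarray(fracs), np.asarray(factors),
                            np.vstack(diffs))


def water_difference_series(spectra: SpectraSet, polymer_pure: Spectrum,
                            anchors: dict[str, float] | None = None,
                            ) -> DifferenceResult:
    """Resolve the water component of each concentration level by
    subtracting the scaled pure-polymer spectrum, anchored at the
    polymer's reference wavenumber."""
    anchors = DEFAULT_ANCHORS if anchors is None else anchors
    labels = {m.polymer for m in spectra.meta}
    if len(labels) != 1:
        raise SpectraError(f"set mixes polymers {sorted(labels)}")
    label = labels.pop()
    if label not in anchors:
        raise SpectraError(f"no anchor wavenumber for polymer {label!r}")
    return _series(spectra, polymer_pure, anchors[label], "water")


def polymer_difference_series(spectra: SpectraSet, water_pure: Spectrum,
                              anchor: float = WATER_ANCHOR,
                              ) -> DifferenceResult:
    """Resolve the polymer component by subtracting the scaled pure-water
    spectrum, anchored at the water combination-band maximum."""
    return _series(spectra, water_pure, anchor, "polymer")


def band_peak(spectrum: Spectrum | np.ndarray, window: tuple[float, float],
              grid: WavenumberGrid | None = None) -> float:
    """Wavenumber of the discrete maximum inside ``window``; ties break
    toward the lower wavenumber."""
    if isinstance(spectrum, Spectrum):
        grid, y = spectrum.grid, spectrum.intensity
    else:
        if grid is None:
            raise SpectraError("grid required for a bare intensity array")
        y = np.asarray(spectrum, dtype=float)
    idx = grid.window_indices(*window)
    return float(grid.values[idx[np.argmax(y[idx])]])


def band_shift_range(result: DifferenceResult,
                     window: tuple[float, float]) -> tuple[float, float]:
    """Peak positions at the lowest and highest nonzero water fractions,
    as an ordered (lo_w, hi_w) pair — decreasing pairs mean a redshift."""
    nz = np.nonzero(result.water_fractions > 0)[0]
    if nz.size < 2:
        raise SpectraError("need at least two nonzero concentrations")
    lo_i, hi_i = nz[0], nz[-1]
    return (band_peak(result.differences[lo_i], window, result.grid),
            band_peak(result.differences[hi_i], window, result.grid))
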